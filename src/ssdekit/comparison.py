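"""Statistical comparison of SSDE estimation methods.

Given a per-case summary table (reference mean D_w / mean SSDE plus the
center-slice and slice-averaged-image estimates), fits ordinary least
squares regressions with R^2 and RMSE, summarizes the per-case errors
(reference - method; a positive error means the method underestimates),
runs a paired Wilcoxon signed-rank test, and correlates errors against
demographic covariates.

The Wilcoxon test computes the exact null distribution of the positive
rank sum (by dynamic programming, identical to full sign-flip enumeration,
with midranks for ties) for up to 25 nonzero differences, and a
tie-corrected normal approximation with continuity correction beyond that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CaseTable",
    "RegressionResult",
    "ErrorDistribution",
    "linear_regression",
    "error_summary",
    "wilcoxon_signed_rank",
    "error_covariate_correlation",
    "compare_methods",
]

REGIONS = ("chest", "abdomen_pelvis", "cap")

_REQUIRED_COLUMNS = (
    "case_id", "region", "mean_dw", "dw_center", "dw_sai",
    "mean_ssde", "ssde_center", "ssde_sai",
)
_COVARIATE_COLUMNS = ("age", "sex", "height", "weight", "bmi")

EXACT_WILCOXON_MAX_N = 25


@dataclass
class RegressionResult:
    """OLS fit y = slope_a * x + intercept_b with R^2 and RMSE."""

    slope_a: float
    intercept_b: float
    r2: float
    rmse: float
    n: int

    def as_dict(self) -> dict:
        return {"a": self.slope_a, "b": self.intercept_b,
                "r2": self.r2, "rmse": self.rmse, "n": self.n}


@dataclass
class ErrorDistribution:
    """Per-case errors (reference - method) with summary statistics."""

    errors: np.ndarray
    median: float
    iqr: float
    mean: float
    sd: float

    def as_dict(self) -> dict:
        return {"median": self.median, "iqr": self.iqr,
                "mean": self.mean, "sd": self.sd, "n": len(self.errors)}


class CaseTable:
    """Validated per-case summary table.

    Wraps a DataFrame with one row per scan: reference values (mean_dw,
    mean_ssde), the center and SAI estimates, a region label, and optional
    demographic covariates.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"case table is missing columns: {missing}")
        if frame["case_id"].duplicated().any():
            raise ValueError("duplicate case_id values")
        bad_region = set(frame["region"]) - set(REGIONS)
        if bad_region:
            raise ValueError(f"unknown region labels: {sorted(bad_region)}")
        numeric = ["mean_dw", "dw_center", "dw_sai",
                   "mean_ssde", "ssde_center", "ssde_sai"]
        values = frame[numeric].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)) or not np.all(values > 0):
            raise ValueError("dose/diameter values must be finite and positive")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "CaseTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.frame)

    def covariates(self) -> list[str]:
        return [c for c in _COVARIATE_COLUMNS if c in self.frame.columns]


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with intercept.

    R^2 = 1 - SSres/SStot; RMSE = sqrt(SSres / n) about the fitted line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("regression needs at least 3 points")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    design = np.column_stack([x, np.ones(n)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - (slope * x + intercept)
    ss_res = float(residuals @ residuals)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RegressionResult(
        slope_a=float(slope),
        intercept_b=float(intercept),
        r2=float(np.clip(r2, 0.0, 1.0)),
        rmse=float(np.sqrt(ss_res / n)),
        n=n,
    )


def raw_rmse(reference, method) -> float:
    """RMSE computed directly between method and reference values."""
    reference = np.asarray(reference, dtype=float)
    method = np.asarray(method, dtype=float)
    if reference.shape != method.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((reference - method) ** 2)))


def error_summary(reference, method) -> ErrorDistribution:
    """Elementwise errors reference - method with summary statistics."""
    reference = np.asarray(reference, dtype=float)
    method = np.asarray(method, dtype=float)
    if reference.shape != method.shape:
        raise ValueError("length mismatch")
    errors = reference - method
    q1, q3 = np.percentile(errors, [25, 75])
    return ErrorDistribution(
        errors=errors,
        median=float(np.median(errors)),
        iqr=float(q3 - q1),
        mean=float(errors.mean()),
        sd=float(errors.std(ddof=1)) if len(errors) > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_ranks(diff: np.ndarray) -> np.ndarray:
    """Midranks of |diff| (ties averaged)."""
    return sps.rankdata(np.abs(diff))


def _exact_wplus_distribution(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact null distribution of W+ on a half-integer rank grid.

    Ranks are midranks, hence multiples of 1/2; doubling them makes every
    achievable W+ an integer index. Returns (counts, scale) where
    ``counts[k]`` is the number of sign assignments with 2*W+ == k. The
    dynamic program is equivalent to enumerating all 2^n assignments.
    """
    doubled = np.round(2 * ranks).astype(int)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:len(counts) - r]
        counts = counts + shifted
    return counts, 2


def wilcoxon_signed_rank(
    sample_a,
    sample_b=None,
    *,
    zero_method: str = "wilcoxon",
) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test.

    Accepts either paired samples or (with ``sample_b=None``) precomputed
    differences. ``zero_method='wilcoxon'`` drops zero differences before
    ranking (default); ``'pratt'`` ranks them but removes their
    contribution from the rank sums.

    Returns ``(W_plus, p_two_sided)`` where W_plus is the positive rank
    sum. Exact for up to 25 nonzero differences, tie- and
    continuity-corrected normal approximation otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    if sample_b is None:
        diff = a
    else:
        b = np.asarray(sample_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        diff = a - b

    if zero_method not in ("wilcoxon", "pratt"):
        raise ValueError("zero_method must be 'wilcoxon' or 'pratt'")
    if zero_method == "wilcoxon":
        diff = diff[diff != 0]
        if len(diff) == 0:
            raise ValueError("all differences are zero; test undefined")
        ranks = _signed_ranks(diff)
    else:
        if not np.any(diff):
            raise ValueError("all differences are zero; test undefined")
        ranks = _signed_ranks(diff)  # zeros included in the ranking
        keep = diff != 0
        diff, ranks = diff[keep], ranks[keep]

    w_plus = float(ranks[diff > 0].sum())
    n = len(diff)

    if n <= EXACT_WILCOXON_MAX_N:
        counts, scale = _exact_wplus_distribution(ranks)
        total = counts.sum()
        k = int(round(scale * w_plus))
        p_le = counts[:k + 1].sum() / total
        p_ge = counts[k:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w_plus, float(p)

    # normal approximation with tie correction and continuity correction
    mu = ranks.sum() / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = (n * (n + 1) * (2 * n + 1)) / 24.0 \
        - (tie_counts ** 3 - tie_counts).sum() / 48.0
    if var <= 0:
        raise ValueError("degenerate variance in Wilcoxon approximation")
    d = w_plus - mu
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return w_plus, p


def error_covariate_correlation(errors, covariate) -> float:
    """Pearson correlation between estimation errors and a covariate."""
    errors = np.asarray(errors, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if errors.shape != covariate.shape:
        raise ValueError("length mismatch")
    if len(errors) < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(errors) == 0 or np.var(covariate) == 0:
        raise ValueError("zero variance")
    return float(np.corrcoef(errors, covariate)[0, 1])


# ---------------------------------------------------------------------------
# full comparison report


def _method_block(reference, method, rmse_mode: str) -> dict:
    reg = linear_regression(method, reference)
    out = reg.as_dict()
    if rmse_mode == "raw":
        out["rmse"] = raw_rmse(reference, method)
    errs = error_summary(reference, method)
    out["errors"] = errs.as_dict()
    return out


def _group_report(frame: pd.DataFrame, rmse_mode: str,
                  covariates: list[str]) -> dict:
    ref_dw = frame["mean_dw"].to_numpy(dtype=float)
    ref_ssde = frame["mean_ssde"].to_numpy(dtype=float)
    report: dict = {"n": len(frame)}
    for target, ref, methods in (
        ("dw", ref_dw, ("dw_center", "dw_sai")),
        ("ssde", ref_ssde, ("ssde_center", "ssde_sai")),
    ):
        block = {}
        errs = {}
        for col in methods:
            vals = frame[col].to_numpy(dtype=float)
            block[col] = _method_block(ref, vals, rmse_mode)
            errs[col] = ref - vals
        center, sai = (errs[m] for m in methods)
        try:
            w, p = wilcoxon_signed_rank(np.abs(center), np.abs(sai))
            block["abs_error_wilcoxon"] = {"w_plus": w, "p": p}
        except ValueError as exc:
            block["abs_error_wilcoxon"] = {"error": str(exc)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            block["shapiro_p"] = {
                m: (float(sps.shapiro(errs[m]).pvalue)
                    if len(frame) >= 3 else None)
                for m in methods
            }
        if covariates:
            corr = {}
            for m in methods:
                corr[m] = {}
                for cov in covariates:
                    vals = pd.to_numeric(frame[cov], errors="coerce")
                    ok = vals.notna().to_numpy()
                    try:
                        corr[m][cov] = error_covariate_correlation(
                            errs[m][ok], vals.to_numpy(dtype=float)[ok])
                    except ValueError:
                        corr[m][cov] = None
            block["error_covariate_r"] = corr
        report[target] = block
    return report


def compare_methods(
    table: CaseTable,
    stratify_by_region: bool = True,
    rmse_mode: str = "residual",
) -> dict:
    """Regression + error-distribution report, per region and aggregated.

    ``rmse_mode`` selects the RMSE convention: ``'residual'`` (about the
    fitted line, default) or ``'raw'`` (directly between method and
    reference). Regions with fewer than 3 cases are skipped with a warning.
    """
    if rmse_mode not in ("residual", "raw"):
        raise ValueError("rmse_mode must be 'residual' or 'raw'")
    frame = table.frame.sort_values("case_id").reset_index(drop=True)
    covariates = table.covariates()
    report: dict = {"rmse_mode": rmse_mode, "groups": {}}
    groups: list[tuple[str, pd.DataFrame]] = []
    if stratify_by_region:
        for region in REGIONS:
            sub = frame[frame["region"] == region]
            if 0 < len(sub) < 3:
                warnings.warn(f"region {region!r} has n={len(sub)} < 3; "
                              "skipped", stacklevel=2)
                continue
            if len(sub):
                groups.append((region, sub))
    groups.append(("aggregated", frame))
    for name, sub in groups:
        report["groups"][name] = _group_report(sub, rmse_mode, covariates)
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten a comparison report into a tidy table of regression cells."""
    rows = []
    for group, block in report["groups"].items():
        for target in ("dw", "ssde"):
            for method, cell in block[target].items():
                if not isinstance(cell, dict) or "a" not in cell:
                    continue
                rows.append({
                    "group": group, "target": target, "method": method,
                    "a": cell["a"], "b": cell["b"],
                    "r2": cell["r2"], "rmse": cell["rmse"], "n": cell["n"],
                })
    return pd.DataFrame(rows)
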