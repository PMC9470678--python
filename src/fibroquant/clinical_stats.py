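"""Clinical reference measures and the index-validation statistics.

Two bedside references serve as gold standards for lymphedema severity:

- **BEI ratio** — 1 kHz bioelectrical impedance asymmetry,
  (unaffected − affected) / unaffected.  Low-frequency current travels
  through interstitial fluid, so the ratio tracks fluid excess.
- **SCDR** — standardized circumference difference ratio,
  (affected − unaffected) / unaffected, measured 5 cm proximal and 5 cm
  distal to the antecubital/popliteal landmark.

The validation compares each of the 19 fibrosis subindices with the BEI and
both SCDRs by partial correlation: variables failing a Kolmogorov–Smirnov
normality check are log-transformed first (with a small positive offset when
non-positive values occur), then the Pearson correlation of
covariate-residualized samples is computed, with two-sided p-values from the
t distribution on n − k − 2 degrees of freedom.  Significance is annotated
with the conventional star notation (* 0.01<p<0.05, ** 0.001<p<0.01,
*** p<0.001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from fibroquant.indices import SUBINDEX_NAMES

__all__ = [
    "PatientRecord",
    "bei_ratio",
    "scdr",
    "normality_check",
    "safe_log_transform",
    "partial_correlation",
    "stars",
    "build_correlation_table",
]


@dataclass
class PatientRecord:
    """One patient's subindex values plus clinical reference measures."""

    patient_id: str
    subindices: dict[str, float]
    bei_ratio: float
    scdr_proximal: float
    scdr_distal: float

    def is_complete(self) -> bool:
        return (
            np.isfinite([self.bei_ratio, self.scdr_proximal, self.scdr_distal]).all()
            and all(np.isfinite(self.subindices.get(k, np.nan)) for k in SUBINDEX_NAMES)
        )


def bei_ratio(unaffected_impedance: float, affected_impedance: float) -> float:
    """(unaffected − affected)/unaffected impedance; dimensionless."""
    if unaffected_impedance <= 0:
        raise ValueError("unaffected impedance must be positive")
    return (unaffected_impedance - affected_impedance) / unaffected_impedance


def scdr(affected_circumference: float, unaffected_circumference: float) -> float:
    """(affected − unaffected)/unaffected limb circumference; dimensionless."""
    if unaffected_circumference <= 0:
        raise ValueError("unaffected circumference must be positive")
    return (affected_circumference - unaffected_circumference) / unaffected_circumference


def normality_check(values: np.ndarray, alpha: float = 0.05) -> tuple[bool, float]:
    """One-sample two-sided KS test against N(sample mean, sample sd).

    Returns (normal?, statistic); normal iff p ≥ alpha.  A zero-variance
    sample is non-normal by convention.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size < 3:
        raise ValueError("normality check needs n >= 3")
    sd = v.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance sample: treated as non-normal")
        return False, float("inf")
    stat, p = stats.kstest(v, "norm", args=(v.mean(), sd))
    return bool(p >= alpha), float(stat)


def safe_log_transform(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Natural log with an automatic positivity offset.

    If any value is ≤ 0, offset = |min| + ε with ε = 1e−6 × range (or 1e−6
    for a constant sample) is added to all values first.  Returns the
    transformed sample and the offset used (0 for all-positive input).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty sample")
    offset = 0.0
    if v.min() <= 0:
        rng = float(v.max() - v.min())
        eps = 1e-6 * rng if rng > 0 else 1e-6
        offset = abs(float(v.min())) + eps
    return np.log(v + offset), offset


def partial_correlation(
    x: np.ndarray, y: np.ndarray, z: np.ndarray | None = None
) -> tuple[float, float]:
    """First-order (or higher) partial correlation of x and y given z.

    Both variables are residualized on [1, z] by least squares and the
    Pearson correlation of the residuals is returned with a two-sided
    p-value from t with n − k − 2 degrees of freedom (k = number of
    covariates).  With z = None or constant this reduces to the plain
    Pearson correlation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    n = x.size
    if z is None:
        zmat = np.empty((n, 0))
    else:
        zmat = np.asarray(z, dtype=np.float64)
        if zmat.ndim == 1:
            zmat = zmat[:, None]
        # drop constant covariate columns: the intercept already absorbs them
        zmat = zmat[:, zmat.std(axis=0) > 0]
    k = zmat.shape[1]
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    design = np.column_stack([np.ones(n), zmat])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("collinear covariates")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    r = max(-1.0, min(1.0, r))
    dof = n - k - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(dof / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return r, float(p)


def stars(p: float) -> str:
    """Significance stars: * 0.01<p<0.05, ** 0.001<p<0.01, *** p<0.001.

    Boundary values (p exactly 0.05, 0.01, 0.001) take the weaker label,
    reading the thresholds as strict inequalities.
    """
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


REFERENCES = ("SCDR_proximal", "SCDR_distal", "BEI")


def build_correlation_table(
    records: list[PatientRecord],
    covariates: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> dict[tuple[str, str], dict[str, float | str]]:
    """Partial-correlation table: 19 subindices × 3 clinical references.

    For every (subindex, reference) pair the two samples are checked for
    normality (KS), log-transformed when non-normal, and correlated
    partially, controlling for a covariate per reference.  By default the
    index–BEI correlations control for the mean SCDR (removing the linear
    effect of limb swelling) and the index–SCDR correlations control for
    the BEI (removing the interstitial-fluid effect).

    Returns {(subindex, reference): {"r", "p", "stars"}}.
    """
    complete = [rec for rec in records if rec.is_complete()]
    if len(complete) < 5:
        raise ValueError("need at least 5 complete records")

    ref_vals = {
        "SCDR_proximal": np.array([r.scdr_proximal for r in complete]),
        "SCDR_distal": np.array([r.scdr_distal for r in complete]),
        "BEI": np.array([r.bei_ratio for r in complete]),
    }
    mean_scdr = (ref_vals["SCDR_proximal"] + ref_vals["SCDR_distal"]) / 2.0
    default_cov = {
        "BEI": mean_scdr,
        "SCDR_proximal": ref_vals["BEI"],
        "SCDR_distal": ref_vals["BEI"],
    }
    cov_vals = dict(default_cov)
    if covariates:
        for ref, name in covariates.items():
            cov_vals[ref] = ref_vals[name] if name in ref_vals else np.asarray(name)

    def prepared(v: np.ndarray) -> np.ndarray:
        normal, _ = normality_check(v, alpha)
        if normal:
            return v
        return safe_log_transform(v)[0]

    table: dict[tuple[str, str], dict[str, float | str]] = {}
    for name in SUBINDEX_NAMES:
        xv = np.array([rec.subindices[name] for rec in complete])
        xp = prepared(xv)
        for ref in REFERENCES:
            yp = prepared(ref_vals[ref])
            r, p = partial_correlation(xp, yp, cov_vals[ref])
            table[(name, ref)] = {"r": r, "p": p, "stars": stars(p)}
    return table
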