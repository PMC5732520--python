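"""Fracture load and stiffness extraction plus cohort validation statistics.

The structural stiffness of a specimen is the least-squares slope of its
force-displacement curve between 20% and 80% of the fracture load. The
fracture load itself is detected from stiffness loss: a reference stiffness
is fitted over the initial linear segment, and fracture is declared at the
first sample whose forward tangent has declined by more than the drop
fraction (20%) of that reference. Mechanically measured curves are smoothed
with a short moving average first, so the same detector serves both the
experimental recordings and the FE-predicted curves and the two metric sets
stay directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
from scipy import stats


class NoFractureError(RuntimeError):
    """The stiffness-drop criterion never fired on this curve."""

    def __init__(self, message: str, curve: "ForceDisplacementCurve | None" = None):
        super().__init__(message)
        self.curve = curve


@dataclass
class ForceDisplacementCurve:
    """Ordered (displacement mm, force N) samples from a test or a solve."""

    displacement: np.ndarray
    force: np.ndarray
    source: str = "mechanical"

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.shape != self.force.shape or self.displacement.size < 3:
            raise ValueError("curve needs matching displacement/force arrays with >= 3 samples")
        if not np.all(np.diff(self.displacement) > 0):
            raise ValueError("displacement samples must be strictly increasing")

    def __len__(self) -> int:
        return len(self.displacement)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"displacement_mm": self.displacement, "force_N": self.force}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "mechanical") -> "ForceDisplacementCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["displacement_mm"].to_numpy(), df["force_N"].to_numpy(), source=source)


@dataclass
class FractureMetrics:
    fracture_load: float
    stiffness: float
    reference_stiffness: float
    detection_index: int
    method: str


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "p_value": self.p_value,
            "n": self.n,
        }


# ---------------------------------------------------------------------------
# stiffness and fracture detection


def stiffness_20_80(curve: ForceDisplacementCurve, fracture_load: float) -> float:
    """Least-squares stiffness over the 20-80% fracture-load window (N/mm)."""
    lo, hi = 0.2 * fracture_load, 0.8 * fracture_load
    mask = (curve.force >= lo) & (curve.force <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"only {int(mask.sum())} samples between 20% and 80% of the fracture load; "
            "a denser curve sampling is needed"
        )
    d, f = curve.displacement[mask], curve.force[mask]
    slope = np.polyfit(d, f, 1)[0]
    return float(slope)


def _forward_tangents(d: np.ndarray, f: np.ndarray) -> np.ndarray:
    return np.diff(f) / np.diff(d)


def _reference_stiffness(d: np.ndarray, f: np.ndarray, deviation: float = 0.05) -> tuple[float, int]:
    """Slope of the initial linear segment and the number of samples used.

    The segment grows from 3 samples while the next forward tangent stays
    within ``deviation`` of the running least-squares slope.
    """
    tangents = _forward_tangents(d, f)
    # robust scatter of the early tangents: exactly zero for clean curves
    # (keeping the strict 5% rule), ~sigma for noisy recordings so a noisy
    # but straight segment keeps growing instead of stopping at 3 samples
    head = tangents[: min(8, len(tangents))]
    scatter = 1.4826 * float(np.median(np.abs(head - np.median(head))))
    m = 3  # samples in the segment
    slope = float(np.polyfit(d[:m], f[:m], 1)[0])
    while m - 1 < len(tangents):
        t_next = tangents[m - 1]
        tol = max(deviation * abs(slope), min(3.5 * scatter, 0.5 * abs(slope)))
        if abs(t_next - slope) > tol:
            break
        m += 1
        slope = float(np.polyfit(d[:m], f[:m], 1)[0])
    return slope, m


def _detect_drop(
    curve: ForceDisplacementCurve,
    force: np.ndarray,
    drop_fraction: float,
    method: str,
    sustain: int = 1,
) -> FractureMetrics:
    d = curve.displacement
    if len(d) < 4:
        raise ValueError("fracture detection needs at least 4 samples")
    reference, seg = _reference_stiffness(d, force)
    tangents = _forward_tangents(d, force)
    threshold = (1.0 - drop_fraction) * reference
    sub = tangents < threshold
    if sustain > 1:
        # require the decline to persist so isolated noisy tangents don't fire
        runs = np.convolve(sub.astype(int), np.ones(sustain, dtype=int), mode="valid")
        sustained = np.zeros_like(sub)
        sustained[: len(runs)] = runs == sustain
        # the criterion may also fire at the very end of the record
        for j in range(max(len(tangents) - sustain + 1, 0), len(tangents)):
            sustained[j] = sub[j:].all()
        sub = sustained
    below = np.where(sub)[0]
    below = below[below >= seg - 1] if below.size else below
    if below.size == 0:
        raise NoFractureError(
            f"no fracture detected: no forward tangent fell below "
            f"{1 - drop_fraction:.0%} of the reference stiffness {reference:.4g} N/mm",
            curve=curve,
        )
    j = int(below[0])
    fracture_load = float(force[j])
    stiffness = stiffness_20_80(
        ForceDisplacementCurve(d, force, source=curve.source), fracture_load
    )
    return FractureMetrics(
        fracture_load=fracture_load,
        stiffness=stiffness,
        reference_stiffness=float(reference),
        detection_index=j,
        method=method,
    )


def fracture_load_fea(
    curve: ForceDisplacementCurve, drop_fraction: float = 0.2
) -> FractureMetrics:
    """FE fracture load: first sample whose tangent stiffness declined >20%."""
    return _detect_drop(curve, curve.force, drop_fraction, method="fea_20pct")


def fracture_load_mechanical(
    curve: ForceDisplacementCurve,
    drop_fraction: float = 0.2,
    smooth_window: int = 5,
) -> FractureMetrics:
    """Mechanical fracture load via the same tangent-drop rule after smoothing.

    A centred moving average (window 5 by default) suppresses measurement
    noise before the rapid stiffness decrease is located, and the decline
    must persist for a full smoothing window of tangents to count as
    fracture rather than as an isolated noisy dip.
    """
    f = _moving_average(curve.force, smooth_window)
    return _detect_drop(curve, f, drop_fraction, method="mech_rapid_drop", sustain=smooth_window)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    half = window // 2
    # odd reflection continues the end slopes, so linear segments (and in
    # particular the initial elastic ramp) are smoothed onto themselves
    padded = np.pad(x, half, mode="reflect", reflect_type="odd")
    kernel = np.ones(2 * half + 1) / (2 * half + 1)
    return np.convolve(padded, kernel, mode="valid")


# ---------------------------------------------------------------------------
# statistics


def linreg(x, y) -> RegressionResult:
    """Ordinary least squares with slope t-test p-value and R^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("regression needs matching x/y with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; regression is undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Mann-Whitney U of group a with a two-sided p-value.

    Exact permutation enumeration (tie-aware) when both groups have <= 8
    observations, otherwise the normal approximation with tie and
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if n1 <= 8 and n2 <= 8:
        mid = n1 * n2 / 2.0
        obs_dev = abs(u1 - mid)
        total = comb(n1 + n2, n1)
        hits = 0
        idx_all = range(n1 + n2)
        rank_cumsum_min = n1 * (n1 + 1) / 2.0
        for combo in combinations(idx_all, n1):
            u = ranks[list(combo)].sum() - rank_cumsum_min
            if abs(u - mid) >= obs_dev - 1e-12:
                hits += 1
        return u1, hits / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u1, float(res.pvalue)


def students_t(a, b) -> tuple[float, float]:
    """Two-sample Student's t test (equal variances)."""
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def multiple_regression(records, response: str, predictors: list[str]):
    """OLS of ``response`` on ``predictors`` with coefficient t-tests."""
    import pandas as pd

    df = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    x = df[predictors].copy()
    for col in predictors:
        if x[col].dtype == object:
            x[col] = pd.factorize(x[col])[0].astype(float)
    xm = np.column_stack([np.ones(len(x)), x.to_numpy(dtype=float)])
    y = df[response].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(xm, y, rcond=None)
    resid = y - xm @ beta
    dof = len(y) - xm.shape[1]
    sigma2 = resid @ resid / max(dof, 1)
    cov = sigma2 * np.linalg.inv(xm.T @ xm)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=max(dof, 1))
    names = ["intercept"] + predictors
    return {
        name: {"coef": float(bi), "se": float(s), "t": float(t), "p": float(p)}
        for name, bi, s, t, p in zip(names, beta, se, tvals, pvals)
    }


# ---------------------------------------------------------------------------
# cohort report

_REQUIRED_FIELDS = (
    "side",
    "age",
    "sex",
    "mech_fracture_load",
    "mech_stiffness",
    "fea_fracture_load",
    "fea_stiffness",
)


@dataclass
class CohortReport:
    regressions: dict = field(default_factory=dict)
    laterality: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "regressions": {k: v.as_dict() for k, v in self.regressions.items()},
            "laterality": self.laterality,
            "summary": self.summary,
        }

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    def to_frame(self):
        import pandas as pd

        rows = [
            {"analysis": name, **reg.as_dict()} for name, reg in self.regressions.items()
        ]
        return pd.DataFrame(rows)


def cohort_report(records) -> CohortReport:
    """The five validation analyses on a specimen cohort.

    Records need per-specimen side, age, sex and the four fracture metrics.
    Emits mech-vs-FE regressions for load and stiffness, load-vs-stiffness
    regressions per source, right-vs-left Mann-Whitney comparisons, and
    load-vs-age regressions per source.
    """
    import pandas as pd

    df = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    if len(df) < 3:
        raise ValueError("cohort_report needs at least 3 specimens")
    missing_cols = [c for c in _REQUIRED_FIELDS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"records missing fields: {missing_cols}")
    bad = df[df[list(_REQUIRED_FIELDS)].isna().any(axis=1)]
    if len(bad):
        ids = bad.index.tolist() if "specimen_id" not in df.columns else bad["specimen_id"].tolist()
        raise ValueError(f"records with missing values for specimens: {ids}")

    rep = CohortReport()
    rep.regressions["fracture_load_mech_vs_fea"] = linreg(
        df["fea_fracture_load"], df["mech_fracture_load"]
    )
    rep.regressions["stiffness_mech_vs_fea"] = linreg(
        df["fea_stiffness"], df["mech_stiffness"]
    )
    rep.regressions["load_vs_stiffness_mech"] = linreg(
        df["mech_stiffness"], df["mech_fracture_load"]
    )
    rep.regressions["load_vs_stiffness_fea"] = linreg(
        df["fea_stiffness"], df["fea_fracture_load"]
    )
    rep.regressions["load_vs_age_mech"] = linreg(df["age"], df["mech_fracture_load"])
    rep.regressions["load_vs_age_fea"] = linreg(df["age"], df["fea_fracture_load"])

    right = df[df["side"] == "right"]
    left = df[df["side"] == "left"]
    for col in ("mech_fracture_load", "mech_stiffness", "fea_fracture_load", "fea_stiffness"):
        if len(right) and len(left):
            u, p = mann_whitney_u(right[col], left[col])
            rep.laterality[col] = {
                "U": u,
                "p": p,
                "right_mean": float(right[col].mean()),
                "left_mean": float(left[col].mean()),
            }
    for col in ("mech_fracture_load", "mech_stiffness", "fea_fracture_load", "fea_stiffness"):
        rep.summary[col] = {"mean": float(df[col].mean()), "sd": float(df[col].std(ddof=1))}
    rep.summary["n"] = int(len(df))
    return rep
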