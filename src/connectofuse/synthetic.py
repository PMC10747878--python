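"""Synthetic parcellated-fMRI cohorts with planted group structure.

Real resting-state cohorts (ABIDE-style multi-site collections) cannot be
redistributed, so this module generates stand-in data in exactly the shapes the
pipeline consumes: one T x R time-series table per subject (T timepoints,
R atlas regions) and a phenotype CSV (site, sex, age, IQ scores, eye status,
handedness).  The group difference is *planted*: cases and controls are drawn
from multivariate normals whose population correlation matrices differ by a
known amount on a known set of ROI pairs, giving every downstream stage a
recoverable ground truth.

Everything here is a pure function of its seed: the same seed reproduces the
cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CovariancePair",
    "SubjectRecord",
    "SyntheticCohort",
    "make_group_covariances",
    "simulate_subject_timeseries",
    "simulate_phenotypes",
    "make_cohort",
    "write_cohort",
]

# smallest admissible eigenvalue of a generated correlation matrix
_EIG_FLOOR = 0.01
# magnitude bound for shared (non-planted) background correlations
_BACKGROUND_SCALE = 0.15

PHENOTYPE_CATEGORICAL = ["site", "sex", "eye_at_scan", "handedness_category"]
PHENOTYPE_NUMERIC = ["age", "fiq", "viq", "piq"]
PHENOTYPE_COLUMNS = PHENOTYPE_CATEGORICAL + PHENOTYPE_NUMERIC

# marginal distributions loosely matched to multi-site resting-state cohort
# demographics (adolescent-skewed ages, IQ near 108 with SD ~15, mostly male,
# mostly right-handed)
_NUMERIC_DISTS = {"age": (15.0, 6.0), "fiq": (108.0, 15.0), "viq": (108.0, 15.0), "piq": (108.0, 15.0)}
_CATEGORICAL_DISTS = {
    "sex": (["M", "F"], [0.8, 0.2]),
    "eye_at_scan": (["open", "closed"], [0.7, 0.3]),
    "handedness_category": (["R", "L", "Ambi"], [0.85, 0.10, 0.05]),
}


@dataclass(frozen=True)
class CovariancePair:
    """Population correlation matrices for the two diagnostic groups.

    Both matrices are symmetric positive definite with unit diagonal; they are
    identical except on ``planted_edges``, where the population correlations
    differ by exactly ``effect_size``.
    """

    sigma_tc: np.ndarray
    sigma_asd: np.ndarray
    planted_edges: list[tuple[int, int]]
    effect_size: float


@dataclass
class SubjectRecord:
    subject_id: str
    timeseries: np.ndarray  # T x R
    phenotype: dict
    label: int  # 1 = case (ASD), 0 = control (TC)


@dataclass
class SyntheticCohort:
    subjects: list[SubjectRecord]
    planted_edges: list[tuple[int, int]]
    seed: int
    n_timepoints: int
    group_sizes: tuple[int, int]  # (n_asd, n_tc)

    @property
    def n_roi(self) -> int:
        return self.subjects[0].timeseries.shape[1]

    def phenotype_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, "label": s.label}
            row.update(s.phenotype)
            rows.append(row)
        return pd.DataFrame(rows)


def _min_eig(m: np.ndarray) -> float:
    return float(np.linalg.eigvalsh(m)[0])


def make_group_covariances(
    n_roi: int,
    n_signal_edges: int,
    effect_size: float,
    base_density: float = 0.1,
    seed: int = 0,
) -> CovariancePair:
    """Construct a pair of group correlation matrices with planted differences.

    The two groups share a sparse random background of weak correlations; on
    ``n_signal_edges`` uniformly sampled ROI pairs the control matrix takes the
    value ``-effect_size/2`` and the case matrix ``+effect_size/2``, so the
    population correlations differ by exactly ``effect_size``.  Positive
    definiteness is enforced without touching the planted entries: the
    background is scaled down (halved repeatedly, dropped to zero if needed)
    until the minimum eigenvalue of both matrices clears a fixed floor of
    0.01, so Cholesky sampling and precision-matrix inversion are always
    well-posed.

    Raises
    ------
    ValueError
        If the requested effect cannot be realized as a valid correlation
        matrix even with zero background; the message reports the maximum
        feasible effect for the drawn edge placement (set by the spectral
        radius of the planted-edge pattern).
    """
    if n_roi < 2:
        raise ValueError("n_roi must be >= 2")
    n_pairs = n_roi * (n_roi - 1) // 2
    if not (1 <= n_signal_edges <= n_pairs):
        raise ValueError(f"n_signal_edges must be in [1, {n_pairs}]")
    if not (0.0 <= effect_size < 1.0):
        raise ValueError("effect_size must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_roi, k=1)
    chosen = rng.choice(n_pairs, size=n_signal_edges, replace=False)
    planted = sorted((int(iu[k]), int(ju[k])) for k in chosen)

    planted_mat = np.zeros((n_roi, n_roi))
    for i, j in planted:
        planted_mat[i, j] = planted_mat[j, i] = 1.0

    half = effect_size / 2.0
    spec_rad = max(abs(_min_eig(planted_mat)), abs(_min_eig(-planted_mat)),
                   float(np.abs(np.linalg.eigvalsh(planted_mat)).max()))
    if half * spec_rad > 1.0 - _EIG_FLOOR:
        max_effect = 2.0 * (1.0 - _EIG_FLOOR) / spec_rad
        raise ValueError(
            "effect_size too large for this edge placement: maximum feasible "
            f"effect is {max_effect:.4f}"
        )

    # shared background correlations on non-planted pairs
    bg = np.zeros((n_roi, n_roi))
    mask = (rng.random(n_pairs) < base_density) & ~np.isin(np.arange(n_pairs), chosen)
    vals = rng.uniform(-_BACKGROUND_SCALE, _BACKGROUND_SCALE, size=n_pairs)
    bg[iu[mask], ju[mask]] = vals[mask]
    bg = bg + bg.T

    # halve the background until both matrices are comfortably positive
    # definite; the planted entries are never altered
    eye = np.eye(n_roi)
    scale = 1.0
    for _ in range(40):
        sigma_tc = eye + scale * bg - half * planted_mat
        sigma_asd = eye + scale * bg + half * planted_mat
        if min(_min_eig(sigma_tc), _min_eig(sigma_asd)) >= _EIG_FLOOR:
            break
        scale /= 2.0
    else:
        sigma_tc = eye - half * planted_mat
        sigma_asd = eye + half * planted_mat
    return CovariancePair(sigma_tc, sigma_asd, planted, effect_size)


def simulate_subject_timeseries(sigma: np.ndarray, n_timepoints: int, seed: int) -> np.ndarray:
    """Draw a T x R table of i.i.d. multivariate-normal timepoints.

    Rows are independent N(0, sigma) draws — a deliberately memoryless stand-in
    for a BOLD time series (no autocorrelation, no hemodynamics).
    """
    sigma = np.asarray(sigma, dtype=float)
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance matrix is not positive definite") from exc
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_timepoints, sigma.shape[0]))
    return z @ chol.T


def simulate_phenotypes(
    labels: list[int] | np.ndarray,
    sites: list[str],
    group_shift: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a phenotype table with the standard multi-site column schema.

    Numeric columns (age, FIQ, VIQ, PIQ) are drawn from normals; an optional
    ``group_shift`` adds a per-column constant to the case group (label 1),
    which plants a phenotypic signal of known size.  Categorical columns are
    multinomial.  No values are missing.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    if not sites:
        raise ValueError("at least one site is required")
    group_shift = dict(group_shift or {})
    unknown = set(group_shift) - set(PHENOTYPE_NUMERIC)
    if unknown:
        raise ValueError(f"group_shift keys must be numeric columns, got {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n = labels.size
    data: dict[str, np.ndarray] = {
        "subject_id": np.array([f"sub-{k:04d}" for k in range(n)]),
        "label": labels,
        "site": rng.choice(sites, size=n),
    }
    for col, (levels, probs) in _CATEGORICAL_DISTS.items():
        data[col] = rng.choice(levels, size=n, p=probs)
    for col, (mu, sd) in _NUMERIC_DISTS.items():
        vals = rng.normal(mu, sd, size=n)
        vals += group_shift.get(col, 0.0) * (labels == 1)
        if col == "age":
            vals = np.clip(vals, 6.0, None)
        data[col] = np.round(vals, 2)
    cols = ["subject_id", "label"] + PHENOTYPE_COLUMNS
    return pd.DataFrame(data)[cols]


def make_cohort(
    n_asd: int = 100,
    n_tc: int = 100,
    n_roi: int = 20,
    n_timepoints: int = 150,
    n_signal_edges: int = 15,
    effect_size: float = 0.4,
    base_density: float = 0.1,
    sites: list[str] | None = None,
    phenotype_shift: dict[str, float] | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Simulate a full two-group cohort.

    Imaging signal (``effect_size`` on ``n_signal_edges`` ROI pairs) and
    phenotypic signal (``phenotype_shift``) are independently switchable, so
    ablations can be validated against known ground truth.  Defaults give a
    mid-sized cohort (100 cases / 100 controls, 20 ROIs, 150 timepoints) with
    a moderate imaging effect and no phenotypic signal.
    """
    sites = sites or ["SITE_A", "SITE_B", "SITE_C"]
    ss = np.random.SeedSequence(seed)
    cov_seed, pheno_seed, ts_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))

    pair = make_group_covariances(n_roi, n_signal_edges, effect_size, base_density, cov_seed)
    labels = np.array([1] * n_asd + [0] * n_tc)
    pheno = simulate_phenotypes(labels, sites, phenotype_shift, pheno_seed)

    ts_ss = np.random.SeedSequence(ts_seed)
    subjects = []
    for k, child in enumerate(ts_ss.spawn(len(labels))):
        sigma = pair.sigma_asd if labels[k] == 1 else pair.sigma_tc
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        ts = simulate_subject_timeseries(sigma, n_timepoints, sub_seed)
        row = pheno.iloc[k]
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                timeseries=ts,
                phenotype={c: row[c] for c in PHENOTYPE_COLUMNS},
                label=int(labels[k]),
            )
        )
    return SyntheticCohort(
        subjects=subjects,
        planted_edges=pair.planted_edges,
        seed=seed,
        n_timepoints=n_timepoints,
        group_sizes=(n_asd, n_tc),
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write one whitespace-delimited time-series file per subject, the
    phenotype CSV, and a JSON manifest recording seed, planted edges and paths.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    ts_dir = outdir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for s in cohort.subjects:
        p = ts_dir / f"{s.subject_id}.txt"
        np.savetxt(p, s.timeseries, fmt="%.6f")
        paths[s.subject_id] = str(p.relative_to(outdir))
    pheno_path = outdir / "phenotypes.csv"
    cohort.phenotype_frame().to_csv(pheno_path, index=False)
    manifest = {
        "seed": cohort.seed,
        "n_timepoints": cohort.n_timepoints,
        "n_roi": cohort.n_roi,
        "group_sizes": list(cohort.group_sizes),
        "planted_edges": [list(e) for e in cohort.planted_edges],
        "phenotypes": str(pheno_path.relative_to(outdir)),
        "timeseries": paths,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
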