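"""Synthetic two-group connectivity cohorts.

Generates seeded cohorts with the statistical structure the downstream
analysis assumes: a sparse symmetric template of nonzero edges, per-subject
multiplicative log-normal strength noise, a designated set of edges whose
population mean is raised in the patient group, per-group global scales
calibrated so the expected mean nonzero strength matches configurable
targets (defaults 0.0499 for patients, 0.0412 for controls), and a strength
floor applied last.  An ``effect_multiplier`` of exactly 1 produces a fully
null cohort: both groups then share the control calibration target, so the
per-edge population distributions are identical.

Cohorts can be emitted either as ready connectivity matrices or as directed
fiber counts (binomial draws with mean strength x samples_per_voxel x
seed-region voxel count) from which the connectome stage rebuilds
strengths, giving a round-trippable end-to-end test path.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .connectome import (
    CONTROL,
    DEFAULT_SAMPLES_PER_VOXEL,
    DEFAULT_THRESHOLD,
    PATIENT,
    Cohort,
    FiberCountData,
    build_matrix,
    write_matrix,
)

N_AFFECTED_DEFAULT = 33


def default_affected_edges() -> list[tuple[int, int]]:
    """The packaged set of 33 region pairs (1-based AAL indices).

    These are the discriminating connections reported for the reference
    cohort, reused here as the default implant locations for 90-region
    simulations.
    """
    with resources.files("connclass.data").joinpath("consensus_edges.csv").open() as fh:
        table = pd.read_csv(fh)
    return [
        (int(a), int(b)) if a < b else (int(b), int(a))
        for a, b in zip(table["index_a"], table["index_b"])
    ]


@dataclass
class SimulationConfig:
    """Cohort generator parameters.

    Strengths for subject s at template edge e are
    ``scale_g * t_e * m_e(g) * g_s * exp(sigma_edge * Z_se)`` with ``t_e``
    drawn log-normally from the template distribution, ``m_e(g)`` the
    affected-edge multiplier (patients only), ``g_s`` a shared per-subject
    log-normal global factor (scale ``subject_global_log_sd``, giving the
    realistic between-subject spread of overall connectivity) and ``Z_se``
    standard normal per edge.  ``scale_g`` is solved per group so the
    expected post-threshold mean nonzero strength equals the group's
    calibration target; with the default targets the patient group is
    globally elevated by roughly 16% on every edge, on top of the implanted
    multiplier.  The default ``effect_multiplier`` of 3.3 places the
    implanted edges at a population Cohen's d of about 1.5 under the
    default noise scales (see :func:`implant_effect_size`).

    ``affected_edges`` may be an explicit list of 1-based region pairs or a
    count to draw at random from the template support; the default for
    90-region cohorts is the packaged 33-pair set.
    """

    n_regions: int = 90
    n_patients: int = 22
    n_controls: int = 26
    density: float = 0.30
    baseline_log_mean: float = float(np.log(0.04))
    baseline_log_sd: float = 0.5
    subject_log_sd: float = 0.6
    subject_global_log_sd: float = 0.1
    affected_edges: list[tuple[int, int]] | int | None = None
    effect_multiplier: float = 3.3
    target_mean_patient: float = 0.0499
    target_mean_control: float = 0.0412
    threshold: float = DEFAULT_THRESHOLD
    emit_counts: bool = False
    samples_per_voxel: int = DEFAULT_SAMPLES_PER_VOXEL
    voxel_counts: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("each group needs at least 2 subjects")
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.effect_multiplier <= 0:
            raise ValueError("effect_multiplier must be positive")
        if self.target_mean_patient <= 0 or self.target_mean_control <= 0:
            raise ValueError("calibration targets must be positive")
        if self.subject_log_sd < 0 or self.subject_global_log_sd < 0:
            raise ValueError("noise scales must be nonnegative")
        if self.voxel_counts is not None:
            self.voxel_counts = np.asarray(self.voxel_counts)
            if np.any(self.voxel_counts <= 0):
                raise ValueError("voxel_counts must be positive")

    def resolved_affected(self) -> list[tuple[int, int]] | int:
        """Affected-edge spec with the default filled in (1-based pairs)."""
        if self.affected_edges is None:
            if self.n_regions == 90:
                return default_affected_edges()
            return N_AFFECTED_DEFAULT
        return self.affected_edges


@dataclass
class CohortTruth:
    """Implanted ground truth of a synthetic cohort."""

    affected_edges: list[tuple[int, int]]  # 1-based (a, b), a < b
    effect_multiplier: float
    # pre-threshold population means per template edge, keyed by 1-based pair
    patient_means: dict[tuple[int, int], float]
    control_means: dict[tuple[int, int], float]


@dataclass
class SyntheticCohort:
    """Generated subjects (strength matrices or fiber counts) plus truth."""

    subjects: list
    labels: np.ndarray
    subject_ids: list[str]
    truth: CohortTruth
    config: SimulationConfig

    def as_cohort(self) -> Cohort:
        """View as an analysis cohort, rebuilding strengths from counts
        through the connectome stage when the cohort was emitted as counts."""
        if self.config.emit_counts:
            matrices = [
                build_matrix(s, threshold=self.config.threshold).strengths
                for s in self.subjects
            ]
        else:
            matrices = self.subjects
        return Cohort(
            matrices=matrices,
            labels=self.labels,
            subject_ids=list(self.subject_ids),
            threshold=self.config.threshold,
        )


def _validate_pairs(
    pairs: list[tuple[int, int]], n_regions: int
) -> list[tuple[int, int]]:
    seen = set()
    out = []
    for a, b in pairs:
        a, b = int(a), int(b)
        if a == b:
            raise ValueError(f"affected edge ({a}, {b}) lies on the diagonal")
        if not (1 <= a <= n_regions and 1 <= b <= n_regions):
            raise ValueError(
                f"affected edge ({a}, {b}) outside regions 1..{n_regions}"
            )
        key = (min(a, b), max(a, b))
        if key in seen:
            raise ValueError(f"affected edge {key} listed twice")
        seen.add(key)
        out.append(key)
    return out


def _truncated_mean_terms(
    mu: np.ndarray, sigma: float, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """E[X; X >= q] and P(X >= q) for X log-normal with E[X]=mu*e^{s^2/2}."""
    if threshold <= 0:
        return mu * np.exp(sigma**2 / 2.0), np.ones_like(mu)
    z = (np.log(mu) - np.log(threshold)) / sigma
    e_kept = mu * np.exp(sigma**2 / 2.0) * norm.cdf(z + sigma)
    p_kept = norm.cdf(z)
    return e_kept, p_kept


def _calibration_scale(
    edge_means: np.ndarray, sigma: float, threshold: float, target: float
) -> float:
    """Solve for the global scale making the expected post-threshold mean
    nonzero strength equal the target."""

    def expected_mean_nonzero(log_scale: float) -> float:
        e, p = _truncated_mean_terms(np.exp(log_scale) * edge_means, sigma, threshold)
        total_p = p.sum()
        if total_p <= 0:
            return 0.0
        return float(e.sum() / total_p)

    def objective(log_scale: float) -> float:
        return expected_mean_nonzero(log_scale) - target

    lo, hi = -20.0, 20.0
    return float(np.exp(brentq(objective, lo, hi, xtol=1e-12)))


def _draw_template(config: SimulationConfig, rng: np.random.Generator):
    """Template support, strengths and affected-edge mask (upper triangle)."""
    R = config.n_regions
    rows, cols = np.triu_indices(R, k=1)
    n_pairs = rows.size
    n_support = int(round(config.density * n_pairs))
    spec = config.resolved_affected()
    if isinstance(spec, int):
        if spec > n_support:
            raise ValueError(
                f"cannot place {spec} affected edges in a support of "
                f"{n_support} edges (density {config.density})"
            )
        support = rng.choice(n_pairs, size=n_support, replace=False)
        affected_pos = rng.choice(support, size=spec, replace=False)
    else:
        pairs = _validate_pairs(spec, R)
        pair_pos = {
            (int(i) + 1, int(j) + 1): p for p, (i, j) in enumerate(zip(rows, cols))
        }
        affected_pos = np.array([pair_pos[p] for p in pairs])
        if affected_pos.size > n_support:
            raise ValueError(
                f"cannot place {affected_pos.size} affected edges in a support "
                f"of {n_support} edges (density {config.density})"
            )
        remaining = np.setdiff1d(np.arange(n_pairs), affected_pos)
        extra = rng.choice(
            remaining, size=n_support - affected_pos.size, replace=False
        )
        support = np.concatenate([affected_pos, extra])
    support = np.sort(support)
    template = rng.lognormal(
        mean=config.baseline_log_mean, sigma=config.baseline_log_sd,
        size=support.size,
    )
    affected_mask = np.isin(support, affected_pos)
    return rows, cols, support, template, affected_mask


def implant_effect_size(config: SimulationConfig) -> float:
    """Median population Cohen's d of the implanted edges.

    Computed analytically from the truncated log-normal strength model
    (post-threshold means and variances) on the template the config's seed
    draws, using the same per-group calibration as the generator.  Useful
    for choosing ``effect_multiplier`` to hit a target per-edge effect size.
    """
    rng = np.random.default_rng(config.seed)
    _, _, _, template, affected = _draw_template(config, rng)
    sigma = float(np.hypot(config.subject_log_sd, config.subject_global_log_sd))
    null = config.effect_multiplier == 1.0
    target_patient = config.target_mean_control if null else config.target_mean_patient
    control_mu = template
    patient_mu = template * np.where(affected, config.effect_multiplier, 1.0)
    scale_c = _calibration_scale(control_mu, sigma, config.threshold,
                                 config.target_mean_control)
    scale_p = _calibration_scale(patient_mu, sigma, config.threshold,
                                 target_patient)

    def moments(mu):
        e1, _ = _truncated_mean_terms(mu, sigma, config.threshold)
        if config.threshold > 0:
            z = (np.log(mu) - np.log(config.threshold)) / sigma
            e2 = mu**2 * np.exp(2 * sigma**2) * norm.cdf(z + 2 * sigma)
        else:
            e2 = mu**2 * np.exp(2 * sigma**2)
        return e1, e2 - e1**2

    e1c, var_c = moments(scale_c * control_mu[affected])
    e1p, var_p = moments(scale_p * patient_mu[affected])
    d = (e1p - e1c) / np.sqrt((var_p + var_c) / 2.0)
    return float(np.median(d))


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a seeded synthetic cohort of connectivity matrices.

    Identical configs (including seed) produce bit-identical cohorts.  With
    ``emit_counts`` set, directed fiber counts are produced instead via
    :func:`generate_fiber_counts`.
    """
    if config.emit_counts:
        return generate_fiber_counts(config)
    return _generate(config, apply_threshold=True)


def _generate(config: SimulationConfig, apply_threshold: bool) -> SyntheticCohort:
    # Calibration always accounts for the threshold truncation; the floor
    # itself is optionally left un-applied so the count-emitting path can
    # hand pre-threshold intended strengths to the binomial sampler (the
    # floor is then applied downstream when matrices are rebuilt).
    rng = np.random.default_rng(config.seed)
    rows, cols, support, template, affected = _draw_template(config, rng)
    # total log-scale noise per entry: independent edge noise plus a shared
    # per-subject global factor (both log-normal)
    sigma_edge = config.subject_log_sd
    sigma_glob = config.subject_global_log_sd
    sigma = float(np.hypot(sigma_edge, sigma_glob))
    null = config.effect_multiplier == 1.0
    target_patient = config.target_mean_control if null else config.target_mean_patient

    control_edge_mu = template
    patient_edge_mu = template * np.where(affected, config.effect_multiplier, 1.0)
    scale_c = _calibration_scale(control_edge_mu, sigma, config.threshold,
                                 config.target_mean_control)
    scale_p = _calibration_scale(patient_edge_mu, sigma, config.threshold,
                                 target_patient)

    R = config.n_regions
    labels = np.array(
        [PATIENT] * config.n_patients + [CONTROL] * config.n_controls, dtype=object
    )
    ids = [f"patient{i + 1:03d}" for i in range(config.n_patients)] + [
        f"control{i + 1:03d}" for i in range(config.n_controls)
    ]
    subjects = []
    for label in labels:
        mu = patient_edge_mu * scale_p if label == PATIENT else control_edge_mu * scale_c
        global_factor = np.exp(sigma_glob * rng.standard_normal())
        vals = mu * global_factor * np.exp(
            sigma_edge * rng.standard_normal(support.size)
        )
        np.clip(vals, None, 1.0, out=vals)
        if apply_threshold:
            vals[vals < config.threshold] = 0.0
        mat = np.zeros((R, R))
        mat[rows[support], cols[support]] = vals
        mat[cols[support], rows[support]] = vals
        subjects.append(mat)

    sig_mean = np.exp(sigma**2 / 2.0)
    pairs_1b = [
        (int(rows[p]) + 1, int(cols[p]) + 1) for p in support
    ]
    truth = CohortTruth(
        affected_edges=[pairs_1b[i] for i in np.flatnonzero(affected)],
        effect_multiplier=config.effect_multiplier,
        patient_means={
            pair: float(scale_p * m * sig_mean)
            for pair, m in zip(pairs_1b, patient_edge_mu)
        },
        control_means={
            pair: float(scale_c * m * sig_mean)
            for pair, m in zip(pairs_1b, control_edge_mu)
        },
    )
    return SyntheticCohort(subjects, labels, ids, truth, config)


def generate_fiber_counts(config: SimulationConfig) -> SyntheticCohort:
    """Generate directed fiber-count cohorts.

    Each subject's intended strengths are drawn exactly as in
    :func:`generate_cohort` (pre-threshold); the directed count from region
    i to j is then Binomial(samples_per_voxel * n_i, strength), so that
    rebuilding strengths through the connectome stage recovers the intended
    values in expectation.  Voxel counts default to a seeded uniform draw
    in 150..500 per region.
    """
    strength_config = SimulationConfig(**{**config.__dict__, "emit_counts": False})
    base = _generate(strength_config, apply_threshold=False)
    # counts and voxel sizes come from a child stream so the intended
    # strengths stay bit-identical to the matrix-emitting path
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    R = config.n_regions
    if config.voxel_counts is not None:
        voxels = np.asarray(config.voxel_counts, dtype=int)
        if voxels.shape != (R,):
            raise ValueError("voxel_counts must have one entry per region")
    else:
        voxels = rng.integers(150, 501, size=R)
    S = config.samples_per_voxel
    counts_subjects = []
    for mat in base.subjects:
        counts = np.zeros((R, R), dtype=np.int64)
        nz_r, nz_c = np.nonzero(np.triu(mat, k=1))
        for i, j in zip(nz_r, nz_c):
            p = min(float(mat[i, j]), 1.0)
            counts[i, j] = rng.binomial(S * int(voxels[i]), p)
            counts[j, i] = rng.binomial(S * int(voxels[j]), p)
        counts_subjects.append(
            FiberCountData(counts=counts, voxel_counts=voxels, samples_per_voxel=S)
        )
    cfg = SimulationConfig(**{**config.__dict__, "emit_counts": True,
                              "voxel_counts": voxels})
    return SyntheticCohort(counts_subjects, base.labels, base.subject_ids,
                           base.truth, cfg)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write one delimited matrix file per subject plus manifest and truth CSVs.

    Returns the manifest path.  Fiber-count cohorts write the count matrix
    and a ``voxel_counts.csv`` alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.csv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "label", "path"])
        for sid, label, subj in zip(
            cohort.subject_ids, cohort.labels, cohort.subjects
        ):
            fname = f"{sid}.csv"
            mat = subj.counts if isinstance(subj, FiberCountData) else subj
            write_matrix(outdir / fname, mat)
            writer.writerow([sid, label, fname])
    if cohort.config.emit_counts:
        np.savetxt(outdir / "voxel_counts.csv",
                   cohort.subjects[0].voxel_counts, fmt="%d")
    with open(outdir / "truth.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["region_a", "region_b", "multiplier"])
        for a, b in cohort.truth.affected_edges:
            writer.writerow([a, b, cohort.truth.effect_multiplier])
    return manifest_path
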