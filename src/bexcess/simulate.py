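"""Synthetic CO2-titration datasets with known in vivo buffer behavior.

The generative model encodes the defining property of the "true" in vivo
base excess: for a subject with whole-body buffer power ``beta_true`` and
metabolic offset ``baseline_sbe``, an acute change of PCO2 moves pH along
the in vivo buffer curve such that

    base_excess(hco3(pH, PCO2), pH, beta_true) == baseline_sbe

at every titration level.  Given PCO2 and the target base excess, the pH
is the unique root of that (strictly increasing in pH) relation, found by
bisection.  Measurement noise is then added to pH and PCO2 and bicarbonate
is recomputed from the noisy pair, mirroring how a blood-gas analyzer
derives HCO3 from measured pH/PCO2.

Subjects within a study draw ``beta_true`` and ``baseline_sbe`` from
study-level distributions; studies in a multi-study dataset may differ in
those distributions, producing the intercept and slope heterogeneity an
ANCOVA is meant to detect.

Reproducibility: each study's random stream is derived by stable hashing
of (shared seed, study id), so adding or reordering studies never changes
another study's draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_CONSTANTS,
    AcidBaseConstants,
    BufferPower,
    base_excess,
    hco3_from_ph_pco2,
    _beta_value,
)

__all__ = [
    "SubjectProfile",
    "StudyDesign",
    "TitrationDataset",
    "SolverError",
    "solve_ph_for_target_sbe",
    "generate_study",
    "generate_multistudy",
    "volunteer_study_design",
]

#: Column order of the observation table (the package's CSV dialect).
OBSERVATION_COLUMNS = [
    "study_id",
    "subject_id",
    "exposure_id",
    "pco2_mmhg",
    "ph",
    "hco3_mmol_l",
]


class SolverError(RuntimeError):
    """The pH root-finder could not bracket a solution."""


@dataclass(frozen=True)
class SubjectProfile:
    """A subject's latent acid-base state: metabolic offset and buffer power."""

    subject_id: str
    baseline_sbe: float
    beta_true: float

    def __post_init__(self) -> None:
        if not self.beta_true > 0:
            raise ValueError("beta_true must be strictly positive")


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of one synthetic CO2-titration experiment.

    Defaults emulate an unanesthetized-volunteer chamber study: 14 subjects
    titrated acutely over an ascending hypercapnic range 40-85 mmHg, a
    population in vivo buffer power of 12.1 +/- 1.5 mmol/L/pH, subject
    metabolic offsets of +/- 1 mmol/L, and small analyzer noise
    (0.005 pH units, 1 mmHg).
    """

    study_id: str
    n_subjects: int = 14
    pco2_levels: tuple[float, ...] = (40.0, 55.0, 70.0, 85.0)
    beta_true_mean: float = 12.1
    beta_true_sd: float = 1.5
    baseline_sbe_mean: float = 0.0
    baseline_sbe_sd: float = 1.0
    ph_noise_sd: float = 0.005
    pco2_noise_sd: float = 1.0
    seed: int = 0
    perturb_hco3: bool = False
    hco3_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        levels = np.asarray(self.pco2_levels, dtype=float)
        if levels.size < 1 or np.any(np.diff(levels) <= 0):
            raise ValueError("pco2_levels must be strictly increasing")
        for name in (
            "beta_true_sd",
            "baseline_sbe_sd",
            "ph_noise_sd",
            "pco2_noise_sd",
            "hco3_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.beta_true_mean > 0:
            raise ValueError("beta_true_mean must be strictly positive")


@dataclass
class TitrationDataset:
    """Observation table plus the design(s) and seed that produced it.

    ``frame`` holds one row per arterial sample with the columns of
    :data:`OBSERVATION_COLUMNS`; ``designs`` and ``seed`` record provenance
    (empty for datasets read from file).
    """

    frame: pd.DataFrame
    designs: tuple[StudyDesign, ...] = ()
    seed: int | None = None
    constants: AcidBaseConstants = field(default=DEFAULT_CONSTANTS, repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in OBSERVATION_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"observation table missing columns: {missing}")
        keys = self.frame[["study_id", "subject_id", "exposure_id"]]
        if keys.duplicated().any():
            raise ValueError("duplicate (study, subject, exposure) triples")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def study_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["study_id"]))

    def subset(self, study_id: str) -> "TitrationDataset":
        sub = self.frame[self.frame["study_id"] == study_id].reset_index(drop=True)
        return TitrationDataset(sub, self.designs, self.seed, self.constants)


def _study_seed_sequence(shared_seed: int, study_id: str) -> np.random.SeedSequence:
    # Stable across sessions and design-list order: hash the study label.
    digest = hashlib.sha256(study_id.encode("utf-8")).digest()
    label_key = int.from_bytes(digest[:8], "big")
    return np.random.SeedSequence([int(shared_seed), label_key])


def solve_ph_for_target_sbe(
    pco2: float | np.ndarray,
    target_sbe: float | np.ndarray,
    beta: float | BufferPower,
    constants: AcidBaseConstants = DEFAULT_CONSTANTS,
    *,
    ph_tol: float = 1e-10,
) -> float | np.ndarray:
    """pH at which base excess at ``beta`` equals ``target_sbe``.

    The objective f(pH) = BE(hco3(pH, PCO2), pH, beta) - target is strictly
    increasing in pH, so bisection on the plausibility bracket [6.5, 8.0]
    converges unconditionally; tolerance 1e-10 pH units gives base-excess
    residuals far below 1e-8 mmol/L.  Vectorized over pco2/target_sbe.
    """
    b = _beta_value(beta)
    constants.check_pco2(pco2)
    pco2_a, target_a = np.broadcast_arrays(
        np.asarray(pco2, dtype=float), np.asarray(target_sbe, dtype=float)
    )
    scalar = pco2_a.ndim == 0
    bshape = pco2_a.shape
    pco2_a = np.atleast_1d(pco2_a).astype(float)
    target_a = np.atleast_1d(target_a).astype(float)

    def f(ph: np.ndarray) -> np.ndarray:
        hco3 = constants.co2_solubility * pco2_a * np.power(
            10.0, ph - constants.pk_prime
        )
        return (hco3 - constants.hco3_ref) + (ph - constants.ph_ref) * b - target_a

    lo = np.full_like(pco2_a, constants.ph_bounds[0])
    hi = np.full_like(pco2_a, constants.ph_bounds[1])
    flo, fhi = f(lo), f(hi)
    bad = (flo > 0) | (fhi < 0)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise SolverError(
            "no sign change on pH bracket "
            f"[{lo[i]}, {hi[i]}]: f(lo)={flo[i]:.4g}, f(hi)={fhi[i]:.4g} "
            f"(pco2={pco2_a[i]}, target_sbe={target_a[i]}, beta={b})"
        )
    # ~54 halvings of the 1.5-unit bracket reach 1e-10
    n_iter = int(np.ceil(np.log2((hi[0] - lo[0]) / ph_tol))) + 1
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        pos = f(mid) > 0
        hi = np.where(pos, mid, hi)
        lo = np.where(pos, lo, mid)
    root = 0.5 * (lo + hi)
    return float(root[0]) if scalar else root.reshape(bshape)


def generate_study(design: StudyDesign) -> TitrationDataset:
    """Simulate one study's titration table from its design.

    Per subject: draw (beta_true, baseline_sbe), solve the noiseless pH at
    each PCO2 level, add Gaussian measurement noise to pH and PCO2, and
    recompute bicarbonate from the noisy pair (default) or perturb the
    noiseless bicarbonate directly (``perturb_hco3=True``).  Fully
    reproducible from ``design.seed``.
    """
    constants = DEFAULT_CONSTANTS
    ss = _study_seed_sequence(design.seed, design.study_id)
    subject_streams = ss.spawn(design.n_subjects)
    levels = np.asarray(design.pco2_levels, dtype=float)
    rows = []
    for i, child in enumerate(subject_streams):
        rng = np.random.default_rng(child)
        beta_true = rng.normal(design.beta_true_mean, design.beta_true_sd)
        while beta_true <= 0:  # truncate the population distribution at 0
            beta_true = rng.normal(design.beta_true_mean, design.beta_true_sd)
        baseline = rng.normal(design.baseline_sbe_mean, design.baseline_sbe_sd)
        subject_id = f"s{i + 1:02d}"
        try:
            ph_true = solve_ph_for_target_sbe(levels, baseline, beta_true, constants)
        except SolverError as err:
            raise SolverError(
                f"{design.study_id}/{subject_id}: {err}"
            ) from err
        ph_noisy = ph_true + rng.normal(0.0, design.ph_noise_sd, size=levels.size)
        pco2_noisy = levels + rng.normal(0.0, design.pco2_noise_sd, size=levels.size)
        if design.perturb_hco3:
            hco3 = hco3_from_ph_pco2(ph_true, levels, constants) + rng.normal(
                0.0, design.hco3_noise_sd, size=levels.size
            )
            ph_out, pco2_out = ph_true, levels
        else:
            hco3 = hco3_from_ph_pco2(ph_noisy, pco2_noisy, constants)
            ph_out, pco2_out = ph_noisy, pco2_noisy
        for k in range(levels.size):
            rows.append(
                (
                    design.study_id,
                    subject_id,
                    f"e{k + 1:02d}",
                    pco2_out[k],
                    ph_out[k],
                    hco3[k],
                )
            )
    frame = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
    return TitrationDataset(frame, designs=(design,), seed=design.seed)


def generate_multistudy(
    designs: Sequence[StudyDesign], shared_seed: int
) -> TitrationDataset:
    """Concatenate independently generated studies under one master seed.

    Each study's stream is derived from (shared_seed, study_id) only, so
    per-study observations are invariant to the order and number of other
    designs.  Duplicate study ids are rejected.
    """
    ids = [d.study_id for d in designs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate study_id in designs: {ids}")
    if not designs:
        raise ValueError("at least one design required")
    seeded = tuple(replace(d, seed=int(shared_seed)) for d in designs)
    frames = [generate_study(d).frame for d in seeded]
    frame = pd.concat(frames, ignore_index=True)
    return TitrationDataset(frame, designs=seeded, seed=int(shared_seed))


def volunteer_study_design(seed: int = 0, **overrides) -> StudyDesign:
    """The default volunteer-like design (14 subjects, 40-85 mmHg) with a seed."""
    return StudyDesign(study_id="volunteers", seed=seed, **overrides)
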