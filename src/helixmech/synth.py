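"""Synthetic step-parameter ensembles and sequence builders.

The generator emulates the statistical structure of a curated ensemble of
protein-DNA crystal structures: per-class Gaussian step-parameter clouds
with B-DNA-like means and class-dependent deformability, optionally
contaminated with a scale-inflated outlier component (the two-component
mixture that the stepwise 3-sd culling procedure presumes), and metadata
(structure ids, resolutions, deposition years) for the curation layer.

The built-in B-DNA parameter tables are synthetic: they are chosen to
reproduce well-established qualitative features of double-helical DNA --
a generic-step twist of 34.1 degrees (the 10.6 bp/turn helical repeat),
pyrimidine-purine steps softest and AT stiffest, the canonical twist
orderings within each chemical class -- not measured from any structural
dataset.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .curation import (
    EnsembleTable,
    StepRecord,
    UNIQUE_DIMERS,
    classify_tetramer,
    complement_step,
    reverse_complement,
)
from .geometry import StepParameters
from .potentials import HarmonicStepPotential, PotentialSet

__all__ = [
    "SynthSpec",
    "sample_ensemble",
    "repeat_sequence",
    "curved_potential_set",
    "bdna_means",
    "bdna_covariance",
    "bdna_potential_set",
    "default_spec",
]

# --------------------------------------------------------------------------
# synthetic B-DNA parameter tables (per unique dimer class)
# --------------------------------------------------------------------------

# twist means chosen so the 16-dimer (sequence-weighted) average is 34.1 deg
# and the classic orderings hold: CG < CA < TA, AG < GG < AA < GA, AT < AC < GC
_TWIST = {
    "AA": 35.0, "AC": 33.5, "AG": 32.5, "AT": 31.5, "CA": 34.7,
    "CC": 33.3, "CG": 33.0, "GA": 36.2, "GC": 34.8, "TA": 36.0,
}
_ROLL = {
    "AA": 0.5, "AC": 0.8, "AG": 3.5, "AT": -0.1, "CA": 4.7,
    "CC": 3.0, "CG": 4.2, "GA": 1.5, "GC": 0.6, "TA": 3.3,
}
_SLIDE = {
    "AA": -0.2, "AC": -0.4, "AG": -0.2, "AT": -0.7, "CA": 0.2,
    "CC": -0.1, "CG": 0.4, "GA": -0.1, "GC": -0.3, "TA": 0.1,
}
# tilt/shift must vanish for self-complementary classes (strand symmetry)
_TILT = {
    "AA": -1.0, "AC": -0.5, "AG": -1.5, "AT": 0.0, "CA": 0.5,
    "CC": 0.3, "CG": 0.0, "GA": -1.2, "GC": 0.0, "TA": 0.0,
}
_SHIFT = {
    "AA": -0.05, "AC": 0.1, "AG": -0.1, "AT": 0.0, "CA": 0.05,
    "CC": -0.1, "CG": 0.0, "GA": -0.15, "GC": 0.0, "TA": 0.0,
}
_RISE = {
    "AA": 3.30, "AC": 3.35, "AG": 3.32, "AT": 3.30, "CA": 3.38,
    "CC": 3.36, "CG": 3.40, "GA": 3.35, "GC": 3.40, "TA": 3.36,
}
# deformability scale per class: V_step ordering TA, CA, CG softest; AT stiffest
_SOFTNESS = {
    "AA": 0.80, "AC": 0.75, "AG": 0.90, "AT": 0.55, "CA": 1.30,
    "CC": 1.00, "CG": 1.25, "GA": 0.85, "GC": 0.90, "TA": 1.50,
}
# base standard deviations: tilt, roll, twist (deg), shift, slide, rise (A)
_BASE_SD = np.array([3.0, 4.5, 4.5, 0.35, 0.5, 0.25])
# correlations respecting strand symmetry: couplings only within the
# sign-flipping block {tilt, shift} and the invariant block {roll, twist, slide}
_CORR = np.eye(6)
_CORR[1, 2] = _CORR[2, 1] = -0.45  # roll-twist
_CORR[2, 4] = _CORR[4, 2] = 0.50  # twist-slide
_CORR[1, 4] = _CORR[4, 1] = -0.30  # roll-slide
_CORR[0, 3] = _CORR[3, 0] = 0.30  # tilt-shift


def bdna_means(dimer_class: str) -> np.ndarray:
    """Synthetic B-DNA mean step parameters of a unique dimer class."""
    d = dimer_class.upper()
    return np.array(
        [_TILT[d], _ROLL[d], _TWIST[d], _SHIFT[d], _SLIDE[d], _RISE[d]]
    )


def bdna_covariance(dimer_class: str) -> np.ndarray:
    """Synthetic covariance: shared correlation pattern, class-scaled spread."""
    sd = _BASE_SD * _SOFTNESS[dimer_class.upper()]
    return _CORR * np.outer(sd, sd)


def _context_perturbation(tetramer: str) -> np.ndarray:
    """Deterministic small context shift for tetramer-level tables.

    A fixed pseudo-random (hash-seeded) perturbation of the central-dimer
    mean, symmetric under reverse complement, mimicking the few-degree
    context dependence of twist and roll.
    """
    canonical = min(tetramer, reverse_complement(tetramer))
    seed = sum(ord(c) * 7**i for i, c in enumerate(canonical)) % (2**31)
    rng = np.random.default_rng(seed)
    delta = np.zeros(6)
    delta[1] = rng.normal(0.0, 1.0)  # roll
    delta[2] = rng.normal(0.0, 1.5)  # twist
    delta[4] = rng.normal(0.0, 0.15)  # slide
    return delta


def bdna_potential_set(level: str = "dimer") -> PotentialSet:
    """Synthetic B-DNA potential set, dimer (10 classes) or tetramer (136)."""
    pots: dict[str, HarmonicStepPotential] = {}
    if level == "dimer":
        for d in UNIQUE_DIMERS:
            pots[d] = HarmonicStepPotential(d, bdna_means(d), bdna_covariance(d))
    elif level == "tetramer":
        for p in "ACGT":
            for a in "ACGT":
                for b in "ACGT":
                    for f in "ACGT":
                        label = classify_tetramer(p, a + b, f)
                        if label in pots:
                            continue
                        central = label[1:3]
                        rc = reverse_complement(central)
                        key = central if central in _TWIST else rc
                        mean = bdna_means(key) + _context_perturbation(label)
                        if central not in _TWIST:
                            # stored reading uses the complementary dimer table
                            mean[0] *= -1.0
                            mean[3] *= -1.0
                        pots[label] = HarmonicStepPotential(
                            label, mean, bdna_covariance(key)
                        )
    else:
        raise ValueError("level must be 'dimer' or 'tetramer'")
    fallback = bdna_potential_set("dimer") if level == "tetramer" else None
    return PotentialSet(level, pots, {"source": "synthetic B-DNA tables"},
                        fallback=fallback)


# --------------------------------------------------------------------------
# ensemble sampling
# --------------------------------------------------------------------------

@dataclass
class SynthSpec:
    """Specification of a synthetic step-parameter ensemble.

    ``class_means``/``class_covs`` are keyed by unique class label (2- or
    4-letter); ``counts`` gives draws per class.  A ``contamination``
    fraction of each class is drawn from the same mean with covariance
    inflated by ``outlier_scale`` squared (two-component Gaussian mixture).
    The same spec and seed always produce an identical table.
    """

    class_means: Mapping[str, np.ndarray]
    class_covs: Mapping[str, np.ndarray]
    counts: Mapping[str, int]
    contamination: float = 0.0
    outlier_scale: float = 4.0
    seed: int = 0

    def __post_init__(self):
        for k, C in self.class_covs.items():
            vals = np.linalg.eigvalsh(np.asarray(C, dtype=float))
            if vals[0] <= 0:
                raise ValueError(f"covariance for class {k} is not SPD")
        for k, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for class {k}")


def default_spec(
    level: str = "dimer",
    n_per_class: int | None = None,
    contamination: float = 0.05,
    outlier_scale: float = 4.0,
    seed: int = 0,
) -> SynthSpec:
    """Default ensemble emulating the curated crystal-structure dataset.

    Dimer level defaults to 5000 examples per unique class (the curated
    dataset exceeds 5000 per step); tetramer level defaults to 300 (each
    tetramer context has hundreds of examples).
    """
    pset = bdna_potential_set(level)
    if n_per_class is None:
        n_per_class = 5000 if level == "dimer" else 300
    means = {k: v.mean for k, v in pset.potentials.items()}
    covs = {k: v.cov for k, v in pset.potentials.items()}
    counts = {k: n_per_class for k in means}
    return SynthSpec(means, covs, counts, contamination, outlier_scale, seed)


def sample_ensemble(spec: SynthSpec) -> EnsembleTable:
    """Draw an :class:`EnsembleTable` from a :class:`SynthSpec`.

    Half of the records (at random) are emitted in the complementary-strand
    reading to exercise the classification layer; the grouping operations
    restore the unique reading, so class statistics are unaffected.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = int(sum(spec.counts.values()))
    n_structs = max(1, n_total // 50)
    struct_ids = [f"SYN{i:05d}" for i in range(n_structs)]
    resolutions = rng.uniform(1.2, 3.5, size=n_structs).round(2)
    years = rng.integers(1995, 2023, size=n_structs)
    records: list[StepRecord] = []
    for label in sorted(spec.class_means):
        n = int(spec.counts.get(label, 0))
        if n == 0:
            continue
        mean = np.asarray(spec.class_means[label], dtype=float)
        cov = np.asarray(spec.class_covs[label], dtype=float)
        n_out = int(round(spec.contamination * n))
        draws = rng.multivariate_normal(mean, cov, size=n - n_out,
                                        method="cholesky")
        if n_out:
            outliers = rng.multivariate_normal(
                mean, cov * spec.outlier_scale**2, size=n_out, method="cholesky"
            )
            draws = np.vstack([draws, outliers])
        if len(label) == 2:
            dimer = label
            flanks = rng.integers(0, 4, size=(n, 2))
            contexts = [("ACGT"[a], "ACGT"[b]) for a, b in flanks]
        elif len(label) == 4:
            dimer = label[1:3]
            contexts = [(label[0], label[3])] * n
        else:
            raise ValueError(f"class label {label!r} must have 2 or 4 letters")
        sidx = rng.integers(0, n_structs, size=n)
        flip = rng.random(n) < 0.5
        for k in range(n):
            rec = StepRecord(
                structure_id=struct_ids[sidx[k]],
                resolution=float(resolutions[sidx[k]]),
                year=int(years[sidx[k]]),
                dimer=dimer,
                context=contexts[k],
                params=StepParameters.from_array(draws[k]),
            )
            records.append(complement_step(rec) if flip[k] else rec)
    table = EnsembleTable(records)
    table.log(
        f"sample_ensemble(seed={spec.seed}, classes={len(spec.class_means)}, "
        f"contamination={spec.contamination})"
    )
    return table


# --------------------------------------------------------------------------
# sequences and curved potential sets
# --------------------------------------------------------------------------

def repeat_sequence(motif: str, total_length: int, phasing: int = 0) -> str:
    """Concatenated repeats of ``motif`` truncated to ``total_length``.

    ``phasing`` rotates the motif before repeating.  A final partial repeat
    earns a warning.
    """
    motif = motif.upper()
    if not set(motif) <= set("ACGT"):
        raise ValueError(f"invalid base in motif {motif!r}")
    if phasing:
        phasing %= len(motif)
        motif = motif[phasing:] + motif[:phasing]
    reps = -(-total_length // len(motif))
    seq = (motif * reps)[:total_length]
    if total_length % len(motif):
        warnings.warn(
            f"length {total_length} is not a multiple of the {len(motif)}-bp "
            "motif: final repeat truncated"
        )
    return seq


def curved_potential_set(
    base_set: PotentialSet,
    curvature_dial: float,
    classes: tuple[str, ...] = ("GC",),
) -> PotentialSet:
    """Copy of ``base_set`` with intrinsic roll added to designated classes.

    Adding ``curvature_dial`` degrees of rest-state roll to classes that
    recur once per helical turn of a repeat sequence gives the sequence a
    known uniform intrinsic curvature (roll is strand-symmetric, so the
    dial applies identically in both readings).
    """
    if curvature_dial < 0:
        raise ValueError("curvature dial must be non-negative")
    out = base_set.copy()
    for cls in classes:
        if cls not in out.potentials:
            raise KeyError(f"class {cls} not in potential set")
        out.potentials[cls].mean[1] += curvature_dial
    out.metadata = dict(out.metadata, curvature_dial=curvature_dial,
                        curved_classes=list(classes))
    return out
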