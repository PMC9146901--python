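"""Harmonic knowledge-based potentials for base-pair steps.

Each sequence class (unique dimer or unique tetramer) gets a harmonic
potential whose rest state is the sample mean of the observed step
parameters and whose stiffness is the inverse of the sample covariance in
kT units:

    E(theta) = 1/2 (theta - mean)^T F (theta - mean),   F = C^-1 [kT]

with C_ij = <theta_i theta_j> - <theta_i><theta_j> (denominator n).  The
scalar deformability of a class is the configuration volume

    V_step = prod_i sqrt(lambda_i(C)) = sqrt(det C)   [deg^3 A^3].

Energies are in kT throughout (kT = 1 internally).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import (
    COMPLEMENT_SIGNS,
    SELF_COMPLEMENTARY_DIMERS,
    UNIQUE_DIMERS,
    classify_dimer,
    classify_tetramer,
    reverse_complement,
)
from .geometry import PARAM_NAMES, StepParameters

__all__ = [
    "HarmonicStepPotential",
    "PotentialSet",
    "GenericMN",
    "fit_potential",
    "config_volume",
    "step_energy",
    "dimer_from_tetramers",
    "generic_mn",
    "helical_repeat",
    "DegeneratePotentialError",
]


class DegeneratePotentialError(ValueError):
    """Energy was requested from a potential with singular covariance."""


def config_volume(C: np.ndarray) -> float:
    """Configuration volume: product of the square roots of the eigenvalues.

    Equals sqrt(det C) for a symmetric PSD covariance.  Eigenvalues below
    -1e-10 (relative to the largest) raise; tiny negatives are clipped.
    """
    C = np.asarray(C, dtype=float)
    vals = np.linalg.eigvalsh(0.5 * (C + C.T))
    scale = max(abs(vals[-1]), 1.0)
    if vals[0] < -1e-10 * scale:
        raise ValueError(f"covariance has negative eigenvalue {vals[0]}")
    vals = np.clip(vals, 0.0, None)
    return float(np.prod(np.sqrt(vals)))


@dataclass
class HarmonicStepPotential:
    """Mean, covariance, stiffness and deformability of one sequence class."""

    label: str
    mean: np.ndarray  # (6,) deg/A
    cov: np.ndarray  # (6, 6)
    n_obs: int = 0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).reshape(6)
        self.cov = np.asarray(self.cov, dtype=float).reshape(6, 6)
        self.cov = 0.5 * (self.cov + self.cov.T)

    @property
    def degenerate(self) -> bool:
        vals = np.linalg.eigvalsh(self.cov)
        return bool(vals[0] <= 1e-12 * max(abs(vals[-1]), 1.0))

    @property
    def stiffness(self) -> np.ndarray:
        """F = C^-1 in kT units; refuses on singular covariance."""
        if self.degenerate:
            raise DegeneratePotentialError(
                f"class {self.label}: covariance is singular; "
                "the harmonic model presumes full-rank dispersion"
            )
        return np.linalg.inv(self.cov)

    @property
    def v_step(self) -> float:
        return config_volume(self.cov)

    def energy(self, p: StepParameters | np.ndarray) -> float:
        arr = p.as_array() if isinstance(p, StepParameters) else np.asarray(p, float)
        d = arr - self.mean
        return float(0.5 * d @ self.stiffness @ d)

    def reflected(self) -> "HarmonicStepPotential":
        """The potential expressed in the complementary-strand reading."""
        S = COMPLEMENT_SIGNS
        label = reverse_complement(self.label)
        return HarmonicStepPotential(
            label, self.mean * S, self.cov * np.outer(S, S), self.n_obs
        )


def fit_potential(
    samples: Sequence[StepParameters] | np.ndarray, label: str = ""
) -> HarmonicStepPotential:
    """Fit mean and covariance (denominator n) to culled samples."""
    arr = np.asarray(
        [s.as_array() if isinstance(s, StepParameters) else s for s in samples],
        dtype=float,
    ).reshape(-1, 6)
    n = arr.shape[0]
    if n < 7:
        raise ValueError(f"need at least 7 samples to fit a potential, got {n}")
    mean = arr.mean(axis=0)
    d = arr - mean
    cov = d.T @ d / n
    return HarmonicStepPotential(label, mean, cov, n_obs=n)


def step_energy(pot: HarmonicStepPotential, p: StepParameters | np.ndarray) -> float:
    """Harmonic step energy in kT; zero at the rest state."""
    return pot.energy(p)


def helical_repeat(mean_twist: float) -> float:
    """Base pairs per helical turn, 360/twist (e.g. 34.1 deg -> 10.6 bp)."""
    if mean_twist <= 0:
        raise ValueError("mean twist must be positive")
    return 360.0 / mean_twist


@dataclass
class PotentialSet:
    """A keyed collection of class potentials at dimer or tetramer level."""

    level: str  # "dimer" | "tetramer"
    potentials: dict[str, HarmonicStepPotential] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    fallback: "PotentialSet | None" = None  # dimer-level fallback for ends

    def __post_init__(self):
        if self.level not in ("dimer", "tetramer"):
            raise ValueError(f"level must be 'dimer' or 'tetramer', got {self.level}")
        cap = 10 if self.level == "dimer" else 136
        if len(self.potentials) > cap:
            raise ValueError(f"{self.level} set has more than {cap} classes")

    def __len__(self) -> int:
        return len(self.potentials)

    def copy(self) -> "PotentialSet":
        pots = {
            k: HarmonicStepPotential(v.label, v.mean.copy(), v.cov.copy(), v.n_obs)
            for k, v in self.potentials.items()
        }
        return PotentialSet(self.level, pots, dict(self.metadata), self.fallback)

    # -- lookup ------------------------------------------------------------
    def potential_for_dimer(self, dimer: str) -> HarmonicStepPotential:
        label, flipped = classify_dimer(dimer)
        if label not in self.potentials:
            raise KeyError(f"no potential for dimer class {label}")
        pot = self.potentials[label]
        return pot.reflected() if flipped else pot

    def potential_for_step(
        self, sequence: str, i: int, circular: bool = False
    ) -> HarmonicStepPotential:
        """Leading-strand potential for step i of a sequence.

        At tetramer level the flanking bases select the class; terminal
        steps of an open chain (no flank on one side) fall back to the
        dimer-level fallback set.
        """
        n = len(sequence)
        if circular:
            dimer = sequence[i % n] + sequence[(i + 1) % n]
        else:
            dimer = sequence[i : i + 2]
        if self.level == "dimer":
            return self.potential_for_dimer(dimer)
        if circular:
            prev = sequence[(i - 1) % n]
            nxt = sequence[(i + 2) % n]
        else:
            if i == 0 or i + 2 >= n:
                if self.fallback is None:
                    raise KeyError(
                        f"step {i} has no tetramer context and no dimer fallback"
                    )
                return self.fallback.potential_for_dimer(dimer)
            prev = sequence[i - 1]
            nxt = sequence[i + 2]
        label = classify_tetramer(prev, dimer, nxt)
        if label not in self.potentials:
            raise KeyError(f"no potential for tetramer class {label}")
        pot = self.potentials[label]
        tet = prev + dimer + nxt
        return pot.reflected() if tet != label else pot

    # -- serialization -----------------------------------------------------
    _SCHEMA = 1

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "schema": self._SCHEMA,
            "level": self.level,
            "metadata": self.metadata,
            "potentials": {
                k: {
                    "mean": v.mean.tolist(),
                    "cov": v.cov.tolist(),
                    "n_obs": v.n_obs,
                }
                for k, v in self.potentials.items()
            },
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PotentialSet":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        obj = json.loads(text)
        pots = {
            k: HarmonicStepPotential(
                k, np.array(v["mean"]), np.array(v["cov"]), v.get("n_obs", 0)
            )
            for k, v in obj["potentials"].items()
        }
        return cls(obj["level"], pots, obj.get("metadata", {}))

    def to_csv(self, path: str | Path | None = None) -> pd.DataFrame:
        """Flat table: one row per class (6 means, 21 covariances, v_step)."""
        iu = np.triu_indices(6)
        rows = []
        for k, v in sorted(self.potentials.items()):
            row = {"label": k, "n_obs": v.n_obs}
            for name, m in zip(PARAM_NAMES, v.mean):
                row[f"mean_{name}"] = m
            for i, j in zip(*iu):
                row[f"cov_{PARAM_NAMES[i]}_{PARAM_NAMES[j]}"] = v.cov[i, j]
            row["v_step"] = v.v_step
            rows.append(row)
        df = pd.DataFrame(rows)
        if path is not None:
            df.to_csv(path, index=False)
        return df

    @classmethod
    def from_csv(cls, path: str | Path, level: str) -> "PotentialSet":
        df = pd.read_csv(path)
        iu = np.triu_indices(6)
        pots = {}
        for row in df.itertuples(index=False):
            mean = np.array([getattr(row, f"mean_{n}") for n in PARAM_NAMES])
            cov = np.zeros((6, 6))
            for i, j in zip(*iu):
                cov[i, j] = cov[j, i] = getattr(
                    row, f"cov_{PARAM_NAMES[i]}_{PARAM_NAMES[j]}"
                )
            pots[row.label] = HarmonicStepPotential(
                row.label, mean, cov, int(row.n_obs)
            )
        return cls(level, pots)


def derive_potential_set(
    table,
    level: str = "dimer",
    cull: bool = True,
    metadata: Mapping | None = None,
) -> PotentialSet:
    """Full pipeline from an :class:`~helixmech.curation.EnsembleTable`.

    Groups usable records by unique class, symmetrizes self-complementary
    groups (both strand readings, so mean tilt and shift vanish), culls at
    three standard deviations, and fits one harmonic potential per class
    with at least 7 surviving members.
    """
    from .curation import cull_3sd, symmetrize_self_complementary

    groups = table.group_by_dimer() if level == "dimer" else table.group_by_tetramer()
    pots: dict[str, HarmonicStepPotential] = {}
    for label, records in groups.items():
        central = label if level == "dimer" else label[1:3]
        if central in SELF_COMPLEMENTARY_DIMERS:
            records = symmetrize_self_complementary(records)
        if cull and len(records) >= 7:
            records, _ = cull_3sd(records)
        if len(records) < 7:
            continue
        pots[label] = fit_potential([r.params for r in records], label)
    return PotentialSet(level, pots, dict(metadata or {}))


def dimer_from_tetramers(
    tset: PotentialSet, dimer: str
) -> tuple[np.ndarray, float]:
    """Context-averaged mean and V_step of a dimer from a tetramer set.

    Unweighted average over the mean step parameters (and configuration
    volumes) of the dimer in all 16 flanking contexts; contexts stored under
    the reverse-complement label are reflected into the requested reading.
    """
    if tset.level != "tetramer":
        raise ValueError("dimer_from_tetramers needs a tetramer-level set")
    dimer = dimer.upper()
    means, vols, missing = [], [], []
    seen: set[str] = set()
    for p in "ACGT":
        for f in "ACGT":
            tet = p + dimer + f
            label = classify_tetramer(p, dimer, f)
            if label in seen and dimer in SELF_COMPLEMENTARY_DIMERS:
                continue  # self-complementary central dimer: 10 unique contexts
            seen.add(label)
            if label not in tset.potentials:
                missing.append(label)
                continue
            pot = tset.potentials[label]
            if tet != label:
                pot = pot.reflected()
            means.append(pot.mean)
            vols.append(pot.v_step)
    if missing:
        raise KeyError(
            f"tetramer set is missing contexts for {dimer}: {sorted(set(missing))}"
        )
    return np.mean(means, axis=0), float(np.mean(vols))


@dataclass
class GenericMN:
    """Average properties of a generic (sequence-averaged) MN step."""

    mean: np.ndarray  # (6,)
    v_step: float
    mode: str  # "sequence-weighted" | "structure-weighted"
    replicates: int = 0
    mean_spread: np.ndarray | None = None  # (6,) sd over replicates
    v_step_spread: float | None = None


def _all_16_dimers() -> list[str]:
    return [a + b for a in "ACGT" for b in "ACGT"]


def generic_mn(
    pset: PotentialSet | None = None,
    mode: str = "sequence-weighted",
    samples_by_class: Mapping[str, np.ndarray] | None = None,
    seed: int | None = None,
    replicates: int = 300,
    subsample_fraction: float = 0.70,
) -> GenericMN:
    """Generic MN step by sequence or structure weighting.

    sequence-weighted: the unweighted average over the 16 dimer means (each
    non-unique dimer contributes its class mean in its own strand reading,
    so tilt and shift cancel); V_step is the average class volume.

    structure-weighted: per replicate, ``floor(subsample_fraction * n_min)``
    raw samples are drawn without replacement from each of the 10 unique
    classes; complementary dimers reuse those samples with tilt/shift
    sign-flipped and self-complementary dimers contribute both strand
    readings.  The pooled mean and pooled-covariance V_step are averaged
    over replicates.
    """
    if mode == "sequence-weighted":
        if pset is None or pset.level != "dimer":
            raise ValueError("sequence-weighted mode needs a dimer-level set")
        means, vols = [], []
        for d in _all_16_dimers():
            pot = pset.potential_for_dimer(d)
            means.append(pot.mean)
            vols.append(pot.v_step)
        return GenericMN(np.mean(means, axis=0), float(np.mean(vols)), mode, 0)
    if mode != "structure-weighted":
        raise ValueError(f"unknown mode {mode!r}")
    if samples_by_class is None:
        raise ValueError("structure-weighted mode needs raw samples per class")
    if replicates < 2:
        raise ValueError("structure-weighted mode needs at least 2 replicates")
    rng = np.random.default_rng(seed)
    arrays = {k: np.asarray(v, dtype=float).reshape(-1, 6) for k, v in samples_by_class.items()}
    for d in UNIQUE_DIMERS:
        if d not in arrays:
            raise KeyError(f"missing raw samples for unique dimer {d}")
    n_draw = int(np.floor(subsample_fraction * min(a.shape[0] for a in arrays.values())))
    if n_draw < 1:
        raise ValueError("too few samples to subsample")
    rep_means = np.empty((replicates, 6))
    rep_vols = np.empty(replicates)
    S = COMPLEMENT_SIGNS
    for r in range(replicates):
        pool = []
        for d in UNIQUE_DIMERS:
            a = arrays[d]
            idx = rng.choice(a.shape[0], size=n_draw, replace=False)
            sub = a[idx]
            if d in SELF_COMPLEMENTARY_DIMERS:
                pool.append(sub)
                pool.append(sub * S)  # both strand readings
            else:
                pool.append(sub)
                pool.append(sub * S)  # the complementary dimer reuses them
        pooled = np.concatenate(pool, axis=0)
        rep_means[r] = pooled.mean(axis=0)
        dd = pooled - rep_means[r]
        rep_vols[r] = config_volume(dd.T @ dd / pooled.shape[0])
    return GenericMN(
        rep_means.mean(axis=0),
        float(rep_vols.mean()),
        mode,
        replicates,
        mean_spread=rep_means.std(axis=0),
        v_step_spread=float(rep_vols.std()),
    )
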