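"""Ring-closure propensities (J-factors) from optimized topoisomer energies.

The ease of cyclization of a sequence is estimated from the statistical
weights of its energy-optimized closed configurations: each topoisomer in
a linking-number window around the relaxed state is optimized and the
Boltzmann weights of the minima are summed,

    W(seq) = sum_{dLk} exp(-E_opt(dLk) / kT).

This rigid-minimum treatment ignores thermal fluctuations about the
minima, so the supported scientific output is the *relative* J-factor of
same-length sequences, W(seq) / W(reference); absolute molar values are
reported only when a calibration constant is supplied and are labeled
calibrated estimates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .energetics import ElectrostaticsParams
from .optimizer import OptimizationResult, build_initial_circle, optimize
from .potentials import PotentialSet

__all__ = ["JFactorResult", "j_factor", "curvature_ranking", "relaxed_linking_number"]


def relaxed_linking_number(sequence: str, potentials: PotentialSet) -> int:
    """Nearest integer to the intrinsic total twist of the circular sequence."""
    total = 0.0
    for i in range(len(sequence)):
        total += potentials.potential_for_step(sequence, i, circular=True).mean[2]
    return int(np.floor(total / 360.0 + 0.5))  # round half-up


@dataclass
class JFactorResult:
    """Boltzmann-weight summary of the scanned topoisomers of one sequence."""

    sequence: str
    relaxed_lk: int
    energies: dict[int, float]  # dLk -> optimized energy, kT
    weight: float  # sum of exp(-E) over the window
    j_relative: float | None = None  # vs a reference sequence
    j_absolute: float | None = None  # mol/L, only with a calibration constant
    partial: bool = False  # some topoisomer failed to converge
    truncation_bound: float = 0.0  # weight bound for topoisomers outside window
    results: dict[int, OptimizationResult] = field(default_factory=dict)


def _optimize_topoisomers(
    sequence: str,
    potentials: PotentialSet,
    window: Sequence[int],
    ep: ElectrostaticsParams | None,
    **opt_kwargs,
) -> tuple[int, dict[int, OptimizationResult], bool]:
    lk0 = relaxed_linking_number(sequence, potentials)
    results: dict[int, OptimizationResult] = {}
    partial = False
    for dlk in window:
        cfg = build_initial_circle(sequence, lk0 + dlk)
        res = optimize(cfg, potentials, ep=ep, relaxed_lk=lk0, **opt_kwargs)
        if not res.converged:
            partial = True
        results[dlk] = res
    return lk0, results, partial


def j_factor(
    sequence: str,
    potentials: PotentialSet,
    window: Sequence[int] = (-1, 0, 1),
    ep: ElectrostaticsParams | None = None,
    calibration: float | None = None,
    reference: "str | JFactorResult | None" = None,
    **opt_kwargs,
) -> JFactorResult:
    """Ring-closure propensity of a circular sequence.

    Optimizes every topoisomer in ``window`` (linking-number offsets around
    the relaxed state; must cover {-1, 0, +1}), sums Boltzmann weights, and
    reports J relative to ``reference`` (a same-length sequence, optimized
    with the same settings, or a precomputed result).  ``calibration``
    converts the aggregate weight to a molar estimate.
    """
    if not {-1, 0, 1} <= set(window):
        raise ValueError("topoisomer window must cover dLk in {-1, 0, +1}")
    lk0, results, partial = _optimize_topoisomers(
        sequence, potentials, window, ep, **opt_kwargs
    )
    energies = {dlk: r.energy.total for dlk, r in results.items()}
    weight = float(np.sum([np.exp(-e) for e in energies.values()]))
    # truncation bound: adding a topoisomer with E >= max scanned changes the
    # aggregate by less than exp(-max E) per side
    bound = float(np.exp(-max(energies.values())))
    j_rel = None
    if reference is not None:
        if isinstance(reference, JFactorResult):
            ref_res = reference
        else:
            if len(reference) != len(sequence):
                raise ValueError("reference sequence must have the same length")
            ref_res = j_factor(
                reference, potentials, window=window, ep=ep, **opt_kwargs
            )
        j_rel = weight / ref_res.weight
    j_abs = calibration * weight if calibration is not None else None
    if partial:
        warnings.warn(f"J-factor for {sequence[:12]}... is partial: "
                      "a topoisomer did not converge")
    return JFactorResult(
        sequence=sequence,
        relaxed_lk=lk0,
        energies=energies,
        weight=weight,
        j_relative=j_rel,
        j_absolute=j_abs,
        partial=partial,
        truncation_bound=bound,
        results=results,
    )


def curvature_ranking(
    sequences: Sequence[str],
    potentials: PotentialSet,
    window: Sequence[int] = (-1, 0, 1),
    ep: ElectrostaticsParams | None = None,
    **opt_kwargs,
) -> list[tuple[str, JFactorResult]]:
    """Sequences of equal length sorted by ring-closure propensity.

    Descending in aggregate Boltzmann weight (equivalently relative J,
    since the weights share a common normalization at fixed length); ties
    broken lexicographically and flagged with a warning.
    """
    lengths = {len(s) for s in sequences}
    if len(lengths) > 1:
        raise ValueError(f"sequences must share one length, got {sorted(lengths)}")
    scored = [
        (s, j_factor(s, potentials, window=window, ep=ep, **opt_kwargs))
        for s in sequences
    ]
    weights = [r.weight for _, r in scored]
    if len(set(np.round(weights, 12))) < len(weights):
        warnings.warn("tied J-factors broken lexicographically")
    return sorted(scored, key=lambda sr: (-sr[1].weight, sr[0]))
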