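"""Fixed-effects Bayesian model selection over candidate architectures.

Under fixed-effects assumptions the group log evidence for a model is the
sum of per-subject free energies; the architecture with the highest summed
free energy wins.  Ties are reported explicitly rather than broken silently.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CoverageError

__all__ = ["BMSResult", "bms_fixed_effects"]

#: summed-F differences below this are treated as ties (log-evidence units)
TIE_TOLERANCE = 1e-9


@dataclass(frozen=True)
class BMSResult:
    model_ids: tuple
    summed_F: dict  # model id -> summed free energy
    winner: int | None  # None on a tie
    tied_models: tuple
    relative_log_evidence: dict  # model id -> F_m - F_best (<= 0)

    @property
    def is_tie(self) -> bool:
        return self.winner is None


def bms_fixed_effects(free_energies: dict) -> BMSResult:
    """Adjudicate between models from per-subject free energies.

    ``free_energies`` maps model id -> {subject id -> F}.  Every subject must
    have an F under every model; gaps raise :class:`CoverageError` listing
    the missing subject x model pairs.
    """
    if not free_energies:
        raise CoverageError("no model evidences supplied")
    model_ids = tuple(sorted(free_energies))
    subjects = sorted({s for per in free_energies.values() for s in per})
    gaps = [
        (m, s)
        for m in model_ids
        for s in subjects
        if s not in free_energies[m]
    ]
    if gaps:
        raise CoverageError(f"missing fits for (model, subject): {gaps}")

    summed = {m: float(sum(free_energies[m].values())) for m in model_ids}
    best = max(summed.values())
    tied = tuple(m for m in model_ids if best - summed[m] <= TIE_TOLERANCE)
    winner = tied[0] if len(tied) == 1 else None
    rel = {m: summed[m] - best for m in model_ids}
    return BMSResult(
        model_ids=model_ids,
        summed_F=summed,
        winner=winner,
        tied_models=tied,
        relative_log_evidence=rel,
    )
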