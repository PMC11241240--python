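"""Receptor-weighted interaction frequencies and fingerprint site selection.

Every receptor contributes equal weight regardless of how many complexes
represent it: a site's weighted frequency is ``(1/R) * sum_i I_i / m_i``
with ``I_i`` the per-complex interaction indicator, ``m_i`` the number of
complexes sharing complex ``i``'s receptor and ``R`` the number of distinct
receptors. This reduces to the plain interacting fraction when every
receptor has exactly one complex, and spans [0, 1] with 1 attained only if
all complexes interact.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from .bw import BWPosition
from .interactions import Contact, filter_by_score

__all__ = [
    "FrequencyTable",
    "Fingerprint",
    "ComplexContacts",
    "weighted_frequency",
    "build_frequency_table",
    "select_sites",
    "auto_threshold",
]

THRESHOLD_GRID_LO = 0.35
THRESHOLD_GRID_HI = 0.60
THRESHOLD_GRID_STEP = 0.05


@dataclass(frozen=True)
class ComplexContacts:
    """One complex's contact list plus the metadata frequencies need."""

    complex_id: str
    receptor_id: str
    activation_state: str
    contacts: tuple[Contact, ...]


@dataclass
class FrequencyTable:
    entries: dict[BWPosition, float]
    n_complexes: int
    n_receptors: int
    score_cutoff: float
    state_filter: str = "all"

    def __post_init__(self) -> None:
        if self.n_receptors > self.n_complexes:
            raise ValueError("n_receptors cannot exceed n_complexes")
        for pos, f in self.entries.items():
            if not -1e-12 <= f <= 1 + 1e-12:
                raise ValueError(f"frequency out of [0,1] at {pos}: {f}")


@dataclass
class Fingerprint:
    sites: list[BWPosition]
    threshold: float
    source: FrequencyTable | None = field(default=None, repr=False)


def weighted_frequency(
    complexes: list[tuple[str, int]],
) -> float:
    """Weighted interaction frequency from (receptor_id, interacts) records."""
    if not complexes:
        raise ValueError("at least one complex required")
    per_receptor = Counter(rid for rid, _ in complexes)
    total = sum(int(bool(flag)) / per_receptor[rid] for rid, flag in complexes)
    return total / len(per_receptor)


def build_frequency_table(
    contact_sets: list[ComplexContacts],
    score_cutoff: float = 0.0,
    state_filter: str = "all",
) -> FrequencyTable:
    """Per-site weighted frequencies over complexes passing the state filter.

    A complex interacts at a site iff at least one of its contacts there
    survives ``filter_by_score(., score_cutoff)``.
    """
    if state_filter == "all":
        kept = list(contact_sets)
    else:
        kept = [cs for cs in contact_sets if cs.activation_state == state_filter]
    if not kept:
        raise ValueError(f"state filter {state_filter!r} excludes all complexes")

    sites: set[BWPosition] = set()
    interacting: list[tuple[str, set[BWPosition]]] = []
    for cs in kept:
        surviving = filter_by_score(list(cs.contacts), score_cutoff)
        pos = {c.bw_position for c in surviving}
        sites |= {c.bw_position for c in cs.contacts}
        interacting.append((cs.receptor_id, pos))

    entries = {
        site: weighted_frequency(
            [(rid, int(site in pos)) for rid, pos in interacting]
        )
        for site in sites
    }
    return FrequencyTable(
        entries=entries,
        n_complexes=len(kept),
        n_receptors=len({cs.receptor_id for cs in kept}),
        score_cutoff=score_cutoff,
        state_filter=state_filter,
    )


def select_sites(table: FrequencyTable, threshold: float) -> Fingerprint:
    """Sites with weighted frequency >= threshold, in BW order.

    Warns when the resulting site count falls outside the 10-15 band that
    fingerprints are sized to.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    sites = sorted(p for p, f in table.entries.items() if f >= threshold)
    if not 10 <= len(sites) <= 15:
        warnings.warn(
            f"fingerprint has {len(sites)} sites (target band is 10-15)",
            stacklevel=2,
        )
    return Fingerprint(sites=sites, threshold=threshold, source=table)


def auto_threshold(
    table: FrequencyTable, min_sites: int = 10, max_sites: int = 15
) -> float:
    """Largest grid threshold in [0.35, 0.60] giving min-max sites.

    Falls back to the grid value whose site count is closest to the band
    (ties resolved toward the larger threshold, i.e. fewer sites).
    """
    if all(f <= 0 for f in table.entries.values()):
        raise ValueError("all frequencies are zero; no threshold is meaningful")
    n_steps = round((THRESHOLD_GRID_HI - THRESHOLD_GRID_LO) / THRESHOLD_GRID_STEP)
    grid = [
        round(THRESHOLD_GRID_LO + k * THRESHOLD_GRID_STEP, 10)
        for k in range(n_steps + 1)
    ]
    counts = {
        t: sum(1 for f in table.entries.values() if f >= t) for t in grid
    }
    feasible = [t for t in grid if min_sites <= counts[t] <= max_sites]
    if feasible:
        return max(feasible)

    def band_distance(t: float) -> int:
        c = counts[t]
        return min_sites - c if c < min_sites else c - max_sites

    best = max(grid, key=lambda t: (-band_distance(t), t))
    warnings.warn(
        f"no grid threshold yields {min_sites}-{max_sites} sites; "
        f"using {best} ({counts[best]} sites)",
        stacklevel=2,
    )
    return best
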