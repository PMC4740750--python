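"""Attribution of Edman N-terminal reads to candidate mature proteins.

Edman degradation reads the mature N-terminus residue by residue. Two kinds
of uncertainty appear in practice: positions with no detectable signal
(written 'x'), which for these proteins usually sit on unmodified cysteines
that the chemistry cannot detect, and low-confidence calls close to the
background level. Reads are anchored at position 0 of each candidate's
mature sequence — Edman chemistry starts at the free N-terminus, so no
internal-offset scanning is performed. Ambiguity is reported, never
resolved: every candidate consistent with a read is returned, which is
exactly what happens when two precursors encode an identical protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .sequence_io import MatureProtein, PrecursorProtein

WILDCARD = "x"


@dataclass(frozen=True)
class EdmanRead:
    """An N-terminal read: residue calls, 'x' blanks, low-confidence set."""

    id: str
    calls: str
    low_confidence: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.calls:
            raise ValueError(f"{self.id}: empty read")
        object.__setattr__(self, "low_confidence", frozenset(self.low_confidence))
        bad = [p for p in self.low_confidence if not 0 <= p < len(self.calls)]
        if bad:
            raise ValueError(
                f"{self.id}: low-confidence position {bad[0]} outside read"
            )


@dataclass(frozen=True)
class EdmanMatch:
    read_id: str
    protein_id: str
    n_compared: int
    n_mismatch: int
    wildcards_on_cys: int
    wildcards_total: int

    @property
    def consistency(self) -> float:
        """Fraction of 'x' blanks sitting on cysteines (1.0 when none)."""
        if self.wildcards_total == 0:
            return 1.0
        return self.wildcards_on_cys / self.wildcards_total


def _compare(
    read: EdmanRead, protein: MatureProtein, low_conf_as_wildcard: bool
) -> EdmanMatch:
    n_compared = n_mismatch = wc_total = wc_cys = 0
    seq = protein.sequence
    for i, call in enumerate(read.calls):
        target = seq[i]
        if call == WILDCARD or (low_conf_as_wildcard and i in read.low_confidence):
            wc_total += 1
            wc_cys += target == "C"
            continue
        n_compared += 1
        n_mismatch += call != target
    return EdmanMatch(
        read.id, protein.id, n_compared, n_mismatch, wc_cys, wc_total
    )


def match_edman(
    read: EdmanRead,
    candidates: list[MatureProtein],
    mode: Literal["strict", "tolerant"] = "strict",
    max_mismatch: int = 1,
    low_conf_as_wildcard: bool = True,
    signal_aware: list[PrecursorProtein] | None = None,
) -> list[EdmanMatch]:
    """All candidates consistent with an Edman read.

    In ``strict`` mode every hard call (neither 'x' nor, by default, a
    low-confidence position) must equal the candidate residue at the same
    offset; ``tolerant`` allows up to ``max_mismatch`` mismatches. Matches
    are sorted by (mismatches, wildcards-on-cysteines descending) so the
    call best explaining the blanks ranks first; ties are preserved in
    candidate order.

    ``signal_aware`` optionally adds the uncleaved precursor N-termini as
    extra comparison targets — a QC check for reads that would only match
    before signal-peptide removal.
    """
    if not candidates:
        raise ValueError("no candidate proteins supplied")
    targets: list[MatureProtein] = [
        c for c in candidates if len(read.calls) < len(c.sequence)
    ]
    if signal_aware:
        targets.extend(
            MatureProtein(f"{p.id}|precursor", p.sequence)
            for p in signal_aware
            if len(read.calls) < len(p.sequence)
        )
    limit = 0 if mode == "strict" else max_mismatch
    hits = [
        m
        for m in (_compare(read, t, low_conf_as_wildcard) for t in targets)
        if m.n_mismatch <= limit
    ]
    hits.sort(key=lambda m: (m.n_mismatch, -m.wildcards_on_cys))
    return hits


def cysteine_consistency(read: EdmanRead, m: MatureProtein) -> float:
    """Fraction of a read's blanks that coincide with cysteines in ``m``.

    Requires a strict match; 1.0 for these proteins means every undetected
    position is explained by an unmodified cysteine.
    """
    result = _compare(read, m, low_conf_as_wildcard=True)
    if result.n_mismatch:
        raise ValueError(
            f"{read.id} does not match {m.id} strictly "
            f"({result.n_mismatch} mismatches)"
        )
    return result.consistency
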