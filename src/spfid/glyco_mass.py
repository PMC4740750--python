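"""Theoretical average masses of mature glycoproteins and mass matching.

The theoretical relative molecular mass (Mr) of a candidate is built up as

    Mr = sum of residue average masses + one water     (linear chain)
         - 2 H per disulfide bridge                    (all bridges formed)
         + n_hexnac * 203.19 + n_hexose * 162.14       (N-glycans)

Each N-linked glycan tree contributes 2 HexNAc units and 3–9 hexoses (the
paucimannose-to-Man9 range of high-mannose N-glycans); with s predicted
sequons, forms with 1..min(s, 3) trees are enumerated. Mass depends only on
the HexNAc/hexose totals, so multi-tree forms are collapsed to distinct
total hexose counts in [3t, 9t].

Observed masses are deconvoluted neutral average masses from intact-protein
electrospray spectra; the default matching tolerance of 2 Da reflects
ion-trap deconvolution accuracy at ~20 kDa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

from .constants import H_ATOM, HEXNAC, HEXOSE, RESIDUE_AVG_MASS, WATER
from .sequence_io import MatureProtein, validate_protein
from .spf_motifs import SequonSet

DEFAULT_TOL_DA = 2.0
DEFAULT_MAX_TREES = 3
HEXOSE_PER_TREE = (3, 9)
HEXNAC_PER_TREE = 2


@dataclass(frozen=True)
class GlycoformMass:
    """One theoretical glycoform: glycan composition and final Mr."""

    id: str
    n_trees: int
    n_hexnac: int
    n_hexose: int
    glycan_mass: float
    total_mr: float


@dataclass(frozen=True)
class ObservedMass:
    sample_id: str
    mr: float
    source: Literal["courtship", "male", "female"]

    def __post_init__(self) -> None:
        if self.mr <= 0:
            raise ValueError(f"{self.sample_id}: mass must be positive")


@dataclass(frozen=True)
class MassMatch:
    observed: ObservedMass
    glycoform: GlycoformMass
    delta: float  # observed - theoretical, Da


def protein_avg_mass(m: MatureProtein | str) -> float:
    """Average mass of the linear (unbridged, unglycosylated) chain in Da."""
    seq = m.sequence if isinstance(m, MatureProtein) else m
    if not seq:
        raise ValueError("empty sequence")
    validate_protein(seq)
    return sum(RESIDUE_AVG_MASS[r] for r in seq) + WATER


def disulfide_corrected_mass(m: MatureProtein) -> float:
    """Chain mass minus 2 H per disulfide bridge, all bridges assumed formed.

    Bridges = floor(n_cys / 2); an odd cysteine count leaves one free thiol
    and triggers a warning, since a fully oxidised SPF scaffold pairs every
    cysteine.
    """
    n_cys = len(m.cys_positions)
    if n_cys % 2:
        warnings.warn(
            f"{m.id}: odd cysteine count ({n_cys}); one thiol left unpaired",
            stacklevel=2,
        )
    return protein_avg_mass(m) - (n_cys // 2) * 2 * H_ATOM


def enumerate_glycoforms(
    m: MatureProtein,
    sequons: SequonSet,
    max_trees: int = DEFAULT_MAX_TREES,
) -> list[GlycoformMass]:
    """All theoretical glycoforms of a mature protein, sorted by Mr.

    Includes the unglycosylated (0-tree) form; with ``s`` sequons and up to
    ``max_trees`` trees the list has 1 + sum_{t=1..min(s,max_trees)} (6t+1)
    entries.
    """
    if max_trees < 1:
        raise ValueError("max_trees must be >= 1")
    base = disulfide_corrected_mass(m)
    lo, hi = HEXOSE_PER_TREE
    forms = [GlycoformMass(m.id, 0, 0, 0, 0.0, base)]
    for t in range(1, min(len(sequons), max_trees) + 1):
        n_hexnac = HEXNAC_PER_TREE * t
        for n_hexose in range(lo * t, hi * t + 1):
            glycan = n_hexnac * HEXNAC + n_hexose * HEXOSE
            forms.append(
                GlycoformMass(m.id, t, n_hexnac, n_hexose, glycan, base + glycan)
            )
    forms.sort(key=lambda g: g.total_mr)
    return forms


def match_masses(
    observed: list[ObservedMass],
    theoretical: list[GlycoformMass],
    tol: float = DEFAULT_TOL_DA,
) -> tuple[list[MassMatch], list[ObservedMass]]:
    """Pair observed deconvoluted masses with theoretical glycoforms.

    Every (observed, glycoform) pair within ``tol`` Da is reported; per
    observation, hits are sorted by absolute mass error. Returns
    ``(matches, unmatched_observations)``.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    matches: list[MassMatch] = []
    unmatched: list[ObservedMass] = []
    for obs in observed:
        hits = [
            MassMatch(obs, g, obs.mr - g.total_mr)
            for g in theoretical
            if abs(obs.mr - g.total_mr) <= tol
        ]
        hits.sort(key=lambda h: abs(h.delta))
        if hits:
            matches.extend(hits)
        else:
            unmatched.append(obs)
    return matches, unmatched
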