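"""Alpha/beta SPF classification by cysteine pattern, and sequon prediction.

SPF precursors encode two-domain three-finger proteins. The two paralog
lineages differ in their disulfide scaffold: alpha SPFs carry an anterior
8-cysteine motif followed by a posterior 6-cysteine motif; beta SPFs carry
10 anterior and 8 posterior cysteines. The two domains are joined by a
cysteine-free linker, so the domain boundary is taken as the midpoint of
the single largest gap between consecutive cysteines (leftmost largest gap
on ties). Anything other than exactly (8, 6) or (10, 8) is left ``unknown``
rather than forced into a class.

N-glycosylation sequons are the canonical N-{P}-[S/T] tripeptides;
overlapping sequons are all reported. Every sequon counts as a potential
site — no predictor score threshold is applied, since the site count is
only used to bound the number of glycan trees.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal

from .sequence_io import MatureProtein

ALPHA_PATTERN = (8, 6)
BETA_PATTERN = (10, 8)

SpfClass = Literal["alpha", "beta", "unknown"]


@dataclass(frozen=True)
class MotifCall:
    id: str
    spf_class: SpfClass
    anterior_cys: int
    posterior_cys: int
    split_index: int  # 0-based boundary used; cys at < split are anterior


@dataclass(frozen=True)
class SequonSet:
    id: str
    positions: tuple[int, ...]  # 0-based Asn indices, sorted

    def __len__(self) -> int:
        return len(self.positions)


def classify_spf(m: MatureProtein) -> MotifCall:
    """Classify a mature protein as alpha, beta or unknown SPF.

    With fewer than two cysteines no inter-cysteine gap exists; the call is
    ``unknown`` with all cysteines counted anterior.
    """
    cys = m.cys_positions
    if len(cys) < 2:
        return MotifCall(m.id, "unknown", len(cys), 0, len(m.sequence))
    gaps = [cys[i + 1] - cys[i] for i in range(len(cys) - 1)]
    i_max = gaps.index(max(gaps))  # leftmost largest gap
    split = (cys[i_max] + cys[i_max + 1] + 1) // 2
    anterior = sum(1 for p in cys if p < split)
    posterior = len(cys) - anterior
    counts = (anterior, posterior)
    if counts == ALPHA_PATTERN:
        spf_class: SpfClass = "alpha"
    elif counts == BETA_PATTERN:
        spf_class = "beta"
    else:
        spf_class = "unknown"
    return MotifCall(m.id, spf_class, anterior, posterior, split)


def find_sequons(m: MatureProtein, allow_pro_x: bool = False) -> SequonSet:
    """All N-glycosylation sequons (Asn positions) in a mature protein.

    The canonical rule excludes proline at Xaa; ``allow_pro_x=True`` relaxes
    this to strict Asn-Xaa-Ser/Thr. Overlapping sequons are all reported; a
    sequon truncated by the end of the sequence is not.
    """
    xaa = "." if allow_pro_x else "[^P]"
    pat = re.compile(f"N(?={xaa}[ST])")
    positions = tuple(mt.start() for mt in pat.finditer(m.sequence))
    return SequonSet(m.id, positions)


def motif_report_row(call: MotifCall, sequons: SequonSet) -> dict:
    """One TSV report row; sequon positions are 1-based in reports."""
    return {
        "id": call.id,
        "spf_class": call.spf_class,
        "anterior_cys": call.anterior_cys,
        "posterior_cys": call.posterior_cys,
        "n_sequons": len(sequons),
        "sequon_positions": ";".join(str(p + 1) for p in sequons.positions),
    }
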