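"""Seeded synthetic data with the structure of the SPF courtship study.

Each generator emulates one arm of the real data:

* **Precursors** — two-domain precursors with a 20-residue signal peptide
  and a planted alpha (8+6) or beta (10+8) cysteine scaffold. The two
  cysteine blocks are separated by a cysteine-free spacer at least
  ``spacer_min`` residues long, so the largest inter-cysteine gap is the
  domain linker by construction. Asparagine is excluded from the background
  alphabet, so the planted N-X-S/T sequons (1–3 per protein) are exactly
  the sequons a scanner will find. Proteins are back-translated to cDNA
  with uniform synonymous codons and flanked by short UTRs.
* **Observed masses** — for secreted proteins, one true glycoform drawn
  uniformly from the theoretical enumeration plus Gaussian noise
  (sd 0.3 Da by default, an ion-trap deconvolution error scale). Courtship
  water contains every secreted protein, male water only the male-specific
  subset, and female water only decoy masses with no SPF truth.
* **Edman reads** — the first ``edman_len`` mature residues with cysteines
  blanked to 'x' (unmodified cysteines give no Edman signal) and an
  occasional low-confidence tail call.
* **Read counts** — a multinomial draw over precursors from known true
  proportions, with unique reads as a binomial thinning.

Every generator is a pure function of its config: a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .edman_matching import EdmanRead
from .expression_quant import ExpressionRow
from .glyco_mass import GlycoformMass, ObservedMass, enumerate_glycoforms
from .sequence_io import (
    MatureProtein,
    PrecursorTranscript,
    strip_signal,
    translate_cds,
)
from .spf_motifs import ALPHA_PATTERN, BETA_PATTERN, SequonSet, find_sequons

# Background alphabet: no C (scaffold only), no N (sequons only).
# Sampling follows natural (Swiss-Prot-like) amino-acid frequencies so
# generated matures land at realistic masses (~110 Da mean residue).
_BACKGROUND = "ADEFGHIKLMPQRSTVWY"
_BACKGROUND_WEIGHTS = np.array(
    [8.25, 5.45, 6.75, 3.86, 7.07, 2.27, 5.96, 5.84, 9.66, 2.42, 4.73,
     3.93, 5.53, 6.56, 5.34, 6.87, 1.09, 2.92]
)
_BACKGROUND_P = _BACKGROUND_WEIGHTS / _BACKGROUND_WEIGHTS.sum()
_HYDROPHOBIC = "AVLIFWM"
_SEQON_XAA = "ADEFGHIKLMQRVWY"  # no P (breaks sequon), no C/N/S/T (clarity)

_CODON_TABLE = unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, ())
    _AA_TO_CODONS[aa] += (codon,)


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror the real data: 14 precursors of which ~2 are alpha,
    180–220-residue mature proteins behind a 20-residue signal peptide,
    1–3 N-glycosylation sequons, 0.3 Da mass noise, 15-cycle Edman reads
    with full cysteine dropout, and ~1.15 M reads over the transcript set.
    """

    seed: int = 0
    n_precursors: int = 14
    alpha_fraction: float = 2 / 14
    signal_len: int = 20
    mature_len_range: tuple[int, int] = (180, 220)
    n_sequons_range: tuple[int, int] = (1, 3)
    spacer_min: int = 20
    mass_noise_sd: float = 0.3
    edman_len: int = 15
    cys_dropout: float = 1.0
    counts_total: int = 1_153_834
    true_props: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.alpha_fraction <= 1:
            raise ValueError("alpha_fraction must be in [0, 1]")
        lo, hi = self.mature_len_range
        if lo > hi or lo <= self.spacer_min:
            raise ValueError("degenerate mature length range")
        if self.true_props is not None:
            if len(self.true_props) != self.n_precursors:
                raise ValueError("true_props length must equal n_precursors")
            if abs(sum(self.true_props) - 1) > 1e-9:
                raise ValueError("true_props must sum to 1")


@dataclass
class PrecursorSet:
    """Generated transcripts with their derived proteins and ground truth."""

    transcripts: list[PrecursorTranscript]
    matures: list[MatureProtein]
    truth: pd.DataFrame  # id, spf_class, group, cys_positions, sequon_positions

    def mature_by_id(self, pid: str) -> MatureProtein:
        return next(m for m in self.matures if m.id == pid)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _random_signal(rng: np.random.Generator, length: int) -> str:
    """Signal-like peptide: Met start, hydrophobic-biased core."""
    out = ["M"]
    for i in range(1, length):
        if 4 <= i <= length - 5:
            out.append(_HYDROPHOBIC[rng.integers(len(_HYDROPHOBIC))])
        else:
            out.append(_BACKGROUND[rng.choice(len(_BACKGROUND), p=_BACKGROUND_P)])
    return "".join(out)


def _plant_scaffold(
    rng: np.random.Generator, cfg: SimConfig, spf_class: str
) -> tuple[str, list[int], list[int]]:
    """One mature sequence with planted cysteine scaffold and sequons."""
    n_ant, n_post = ALPHA_PATTERN if spf_class == "alpha" else BETA_PATTERN
    length = int(rng.integers(*cfg.mature_len_range, endpoint=True))

    lead = int(rng.integers(4, 13))
    ant_gaps = rng.integers(2, 7, size=n_ant - 1)
    post_gaps = rng.integers(2, 7, size=n_post - 1)
    spacer = int(rng.integers(cfg.spacer_min + 1, cfg.spacer_min + 16))
    cys: list[int] = [lead]
    for g in ant_gaps:
        cys.append(cys[-1] + int(g))
    cys.append(cys[-1] + spacer)
    for g in post_gaps:
        cys.append(cys[-1] + int(g))
    if cys[-1] >= length - 3:
        raise ValueError(
            f"mature length {length} too short for scaffold plus spacer"
        )

    seq = [
        _BACKGROUND[i]
        for i in rng.choice(len(_BACKGROUND), size=length, p=_BACKGROUND_P)
    ]
    for p in cys:
        seq[p] = "C"

    n_seq = int(rng.integers(*cfg.n_sequons_range, endpoint=True))
    cys_set = set(cys)
    candidates = [
        i
        for i in range(length - 2)
        if not cys_set & {i, i + 1, i + 2}
    ]
    rng.shuffle(candidates)
    sequons: list[int] = []
    for i in candidates:
        if len(sequons) == n_seq:
            break
        if all(abs(i - j) >= 3 for j in sequons):
            sequons.append(i)
    sequons.sort()
    for i in sequons:
        seq[i] = "N"
        seq[i + 1] = _SEQON_XAA[rng.integers(len(_SEQON_XAA))]
        seq[i + 2] = "ST"[rng.integers(2)]
    return "".join(seq), cys, sequons


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [
        _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))]
        for aa in protein
    ]
    return "".join(codons) + "TAA"


def generate_precursors(cfg: SimConfig) -> PrecursorSet:
    """Simulate precursor transcripts and their ground-truth annotation."""
    rng = _rng(cfg, 1)
    n_alpha = round(cfg.alpha_fraction * cfg.n_precursors)
    classes = ["beta"] * (cfg.n_precursors - n_alpha) + ["alpha"] * n_alpha

    transcripts, matures, rows = [], [], []
    for k, spf_class in enumerate(classes, start=1):
        pid = f"SYN{k:02d}"
        mature_seq, cys, sequons = _plant_scaffold(rng, cfg, spf_class)
        protein = _random_signal(rng, cfg.signal_len) + mature_seq
        cds = _back_translate(rng, protein)
        utr5 = "".join("ACGT"[i] for i in rng.integers(4, size=int(rng.integers(10, 31))))
        utr3 = "".join("ACGT"[i] for i in rng.integers(4, size=int(rng.integers(20, 61))))
        t = PrecursorTranscript(
            pid, utr5 + cds + utr3, len(utr5), len(utr5) + len(cds)
        )
        transcripts.append(t)
        matures.append(strip_signal(translate_cds(t, cfg.signal_len)))
        group = "alpha" if spf_class == "alpha" else "courtship_beta"
        rows.append(
            {
                "id": pid,
                "spf_class": spf_class,
                "group": group,
                "mature_len": len(mature_seq),
                "cys_positions": ";".join(map(str, cys)),
                "sequon_positions": ";".join(map(str, sequons)),
            }
        )
    # the lowest-expressed beta precursor doubles as the male-specific one
    truth = pd.DataFrame(rows)
    beta_idx = truth.index[truth.spf_class == "beta"]
    if len(beta_idx):
        truth.loc[beta_idx[-1], "group"] = "male_specific"
    return PrecursorSet(transcripts, matures, truth)


def generate_observed_masses(
    precursors: PrecursorSet, cfg: SimConfig, n_female_decoys: int = 2
) -> tuple[list[ObservedMass], pd.DataFrame]:
    """Noisy deconvoluted masses with per-sample glycoform ground truth.

    Courtship water carries one observation per secreted protein, male
    water repeats the male-specific subset, and female water holds only
    decoy masses with an empty truth id.
    """
    rng = _rng(cfg, 2)
    observed: list[ObservedMass] = []
    rows = []
    groups = dict(zip(precursors.truth.id, precursors.truth.group))
    for m in precursors.matures:
        forms = enumerate_glycoforms(m, find_sequons(m))
        true_form: GlycoformMass = forms[rng.integers(len(forms))]
        sources = ["courtship"]
        if groups[m.id] == "male_specific":
            sources.append("male")
        for source in sources:
            sid = f"{source}_{m.id}"
            mr = true_form.total_mr + rng.normal(0.0, cfg.mass_noise_sd)
            observed.append(ObservedMass(sid, mr, source))
            rows.append(
                {
                    "sample_id": sid,
                    "truth_id": m.id,
                    "n_trees": true_form.n_trees,
                    "n_hexose": true_form.n_hexose,
                    "true_mr": true_form.total_mr,
                }
            )
    for d in range(n_female_decoys):
        sid = f"female_decoy{d + 1}"
        observed.append(
            ObservedMass(sid, float(rng.uniform(10_000, 15_000)), "female")
        )
        rows.append(
            {"sample_id": sid, "truth_id": "", "n_trees": 0, "n_hexose": 0,
             "true_mr": np.nan}
        )
    return observed, pd.DataFrame(rows)


def generate_edman_reads(
    precursors: PrecursorSet, cfg: SimConfig, low_conf_tail_prob: float = 0.3
) -> tuple[list[EdmanRead], pd.DataFrame]:
    """One N-terminal read per mature protein, cysteines blanked to 'x'."""
    rng = _rng(cfg, 3)
    reads, rows = [], []
    for m in precursors.matures:
        if cfg.edman_len >= len(m.sequence):
            raise ValueError(
                f"{m.id}: read length {cfg.edman_len} >= mature length"
            )
        window = m.sequence[: cfg.edman_len]
        calls = "".join(
            "x" if r == "C" and rng.random() < cfg.cys_dropout else r
            for r in window
        )
        low_conf: frozenset[int] = frozenset()
        if rng.random() < low_conf_tail_prob:
            n_tail = int(rng.integers(1, 3))
            low_conf = frozenset(
                i
                for i in range(cfg.edman_len - n_tail, cfg.edman_len)
                if calls[i] != "x"
            )
        reads.append(EdmanRead(f"read_{m.id}", calls, low_conf))
        rows.append({"read_id": f"read_{m.id}", "truth_id": m.id})
    return reads, pd.DataFrame(rows)


def generate_read_counts(
    cfg: SimConfig, precursors: PrecursorSet
) -> tuple[list[ExpressionRow], np.ndarray]:
    """Multinomial read counts over precursors plus the true proportions.

    With no ``true_props`` in the config, proportions are drawn once from a
    symmetric Dirichlet(0.5) — a strongly uneven profile like the real
    cloacal expression table.
    """
    rng = _rng(cfg, 4)
    n = len(precursors.transcripts)
    if cfg.true_props is not None:
        props = np.asarray(cfg.true_props, dtype=float)
    else:
        props = rng.dirichlet(np.full(n, 0.5))
    counts = rng.multinomial(cfg.counts_total, props)
    rows = [
        ExpressionRow(
            t.id,
            t.length_bp,
            int(c),
            int(rng.binomial(int(c), 0.5)),
        )
        for t, c in zip(precursors.transcripts, counts)
    ]
    return rows, props


def write_dataset(precursors: PrecursorSet, cfg: SimConfig, out_dir) -> None:
    """Write precursors.fasta, truth.tsv, observed.tsv, edman.tsv, counts.tsv."""
    from pathlib import Path

    from .sequence_io import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "precursors.fasta", precursors.transcripts)
    precursors.truth.to_csv(out / "truth.tsv", sep="\t", index=False)

    observed, mass_truth = generate_observed_masses(precursors, cfg)
    pd.DataFrame(
        {
            "sample_id": [o.sample_id for o in observed],
            "mr_da": [o.mr for o in observed],
            "source": [o.source for o in observed],
        }
    ).to_csv(out / "observed.tsv", sep="\t", index=False)
    mass_truth.to_csv(out / "observed_truth.tsv", sep="\t", index=False)

    reads, read_truth = generate_edman_reads(precursors, cfg)
    pd.DataFrame(
        {
            "read_id": [r.id for r in reads],
            "calls": [r.calls for r in reads],
            "low_conf_positions": [
                ";".join(str(p + 1) for p in sorted(r.low_confidence))
                for r in reads
            ],
        }
    ).to_csv(out / "edman.tsv", sep="\t", index=False)
    read_truth.to_csv(out / "edman_truth.tsv", sep="\t", index=False)

    counts, props = generate_read_counts(cfg, precursors)
    pd.DataFrame(
        {
            "id": [r.id for r in counts],
            "length_bp": [r.length_bp for r in counts],
            "total_reads": [r.total_reads for r in counts],
            "unique_reads": [r.unique_reads for r in counts],
            "true_prop": props,
        }
    ).to_csv(out / "counts.tsv", sep="\t", index=False)
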