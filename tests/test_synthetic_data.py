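"""Determinism and full-pipeline recovery of the synthetic-data generators."""

from dataclasses import replace

import numpy as np
import pytest

from spfid import (
    classify_spf,
    compute_rpkm,
    enumerate_glycoforms,
    find_sequons,
    match_edman,
    match_masses,
    relative_expression,
    write_fasta,
)
from spfid.synthetic_data import (
    SimConfig,
    generate_edman_reads,
    generate_observed_masses,
    generate_precursors,
    generate_read_counts,
    write_dataset,
)


def test_fixed_seed_byte_identical_fasta(tmp_path):
    cfg = SimConfig(seed=1, n_precursors=14)
    p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
    write_fasta(p1, generate_precursors(cfg).transcripts)
    write_fasta(p2, generate_precursors(cfg).transcripts)
    assert p1.read_bytes() == p2.read_bytes()


def test_different_seeds_differ():
    a = generate_precursors(SimConfig(seed=1))
    b = generate_precursors(SimConfig(seed=2))
    assert a.transcripts[0].cdna != b.transcripts[0].cdna


def test_mature_length_too_short_errors():
    cfg = SimConfig(seed=0, mature_len_range=(60, 62), spacer_min=50)
    with pytest.raises(ValueError, match="too short"):
        generate_precursors(cfg)


def test_mature_lengths_in_configured_range(precursor_set, sim_config):
    lo, hi = sim_config.mature_len_range
    for m in precursor_set.matures:
        assert lo <= len(m.sequence) <= hi


def test_generated_glycoproteins_fall_in_20_25_kda_window(precursor_set):
    """Secreted glycosylated matures are 20-25 kDa-class proteins.

    Gel windows are coarse (~1 kDa); the check is that every protein's
    lightest glycosylated form sits in or at the edge of the window and
    that the bulk of the distribution is inside it.
    """
    import numpy as np

    lightest = []
    for m in precursor_set.matures:
        forms = enumerate_glycoforms(m, find_sequons(m))
        lightest.append(min(g.total_mr for g in forms if g.n_trees >= 1))
    lightest = np.array(lightest)
    assert (lightest >= 20_000).all() and (lightest <= 26_000).all()
    assert 20_000 <= np.median(lightest) <= 25_000


def test_noise_free_masses_equal_theoretical(precursor_set):
    cfg = SimConfig(seed=1, mass_noise_sd=0.0)
    observed, truth = generate_observed_masses(precursor_set, cfg)
    by_id = {o.sample_id: o.mr for o in observed}
    spf = truth[truth.truth_id != ""]
    for _, row in spf.iterrows():
        assert by_id[row.sample_id] == pytest.approx(row.true_mr, abs=1e-12)


def test_female_rows_are_decoys_only(precursor_set, sim_config):
    observed, truth = generate_observed_masses(precursor_set, sim_config)
    females = {o.sample_id for o in observed if o.source == "female"}
    assert females
    assert (truth.loc[truth.sample_id.isin(females), "truth_id"] == "").all()


def test_courtship_superset_of_male(precursor_set, sim_config):
    observed, truth = generate_observed_masses(precursor_set, sim_config)
    male_ids = {
        r.truth_id
        for _, r in truth.iterrows()
        if r.sample_id.startswith("male_")
    }
    courtship_ids = {
        r.truth_id
        for _, r in truth.iterrows()
        if r.sample_id.startswith("courtship_")
    }
    assert male_ids and male_ids <= courtship_ids


def test_full_cys_dropout_blanks_exactly_the_cysteines(
    precursor_set, sim_config
):
    reads, _ = generate_edman_reads(precursor_set, sim_config)
    for read, m in zip(reads, precursor_set.matures):
        window = m.sequence[: sim_config.edman_len]
        expected_x = {i for i, c in enumerate(window) if c == "C"}
        assert {i for i, c in enumerate(read.calls) if c == "x"} == expected_x


def test_counts_sum_and_determinism(precursor_set, sim_config):
    rows1, props = generate_read_counts(sim_config, precursor_set)
    rows2, _ = generate_read_counts(sim_config, precursor_set)
    assert sum(r.total_reads for r in rows1) == sim_config.counts_total
    assert [r.total_reads for r in rows1] == [r.total_reads for r in rows2]
    assert props.sum() == pytest.approx(1.0)


def test_explicit_true_props_respected(precursor_set):
    n = len(precursor_set.transcripts)
    props = tuple([0.5] + [0.5 / (n - 1)] * (n - 1))
    cfg = SimConfig(seed=3, true_props=props)
    _, got = generate_read_counts(cfg, precursor_set)
    assert got == pytest.approx(np.array(props))


def test_full_pipeline_recovery(tmp_path, precursor_set, sim_config):
    """Classes, sequons, glycoforms, Edman sources and proportions all
    round-trip through the analysis from one seeded simulation."""
    ps, cfg = precursor_set, sim_config
    truth_class = dict(zip(ps.truth.id, ps.truth.spf_class))
    theoretical = []
    for m in ps.matures:
        assert classify_spf(m).spf_class == truth_class[m.id]
        theoretical.extend(enumerate_glycoforms(m, find_sequons(m)))

    observed, mass_truth = generate_observed_masses(ps, cfg)
    matches, _ = match_masses(observed, theoretical, tol=2.0)
    top: dict[str, object] = {}
    for mm in matches:
        top.setdefault(mm.observed.sample_id, mm.glycoform)
    for _, row in mass_truth[mass_truth.truth_id != ""].iterrows():
        g = top[row.sample_id]
        assert g.id == row.truth_id and g.n_hexose == row.n_hexose

    reads, read_truth = generate_edman_reads(ps, cfg)
    for read, (_, row) in zip(reads, read_truth.iterrows()):
        hits = match_edman(read, ps.matures)
        assert hits[0].protein_id == row.truth_id

    rows, props = generate_read_counts(cfg, ps)
    rows = relative_expression(compute_rpkm(rows, cfg.counts_total))
    n = cfg.counts_total
    for r, p in zip(rows, props):
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(r.total_reads / n - p) <= 3 * sd + 1e-12

    write_dataset(ps, cfg, tmp_path / "out")
    for name in (
        "precursors.fasta", "truth.tsv", "observed.tsv", "edman.tsv",
        "counts.tsv",
    ):
        assert (tmp_path / "out" / name).exists()
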