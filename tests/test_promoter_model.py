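"""PWM construction, scanning (with brute-force oracle), and discovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecf41.locus_context import GeneRecord
from ecf41.promoter_model import (
    BipartiteMotifModel,
    assign_hits,
    build_pwm,
    consensus,
    discover_bipartite_motif,
    extract_upstream,
    information_content,
    reverse_complement,
    scan,
    spacer_stats,
)
from ecf41.synthetic_data import generator_motif_model, plant_site


# ---------------------------------------------------------------------------
# upstream windows
# ---------------------------------------------------------------------------

class TestExtractUpstream:
    def _replicon(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list("ACGT"), size=n))

    def test_plus_strand_window(self):
        seq = self._replicon()
        gene = GeneRecord("g", "r", 1000, 1500, "+")
        win = extract_upstream(gene, seq, 250)
        assert win.sequence == seq[749:999]
        assert win.window_length == 250

    def test_minus_strand_window_is_reverse_complement(self):
        seq = self._replicon()
        gene = GeneRecord("g", "r", 100, 500, "-")
        win = extract_upstream(gene, seq, 250)
        assert win.sequence == reverse_complement(seq[500:750])

    def test_window_truncated_at_replicon_start(self):
        seq = self._replicon()
        gene = GeneRecord("g", "r", 100, 500, "+")
        win = extract_upstream(gene, seq, 250)
        assert win.window_length == 99
        assert win.sequence == seq[:99]

    def test_gene_flush_with_boundary_gives_empty_window(self):
        seq = self._replicon()
        gene = GeneRecord("g", "r", 1, 300, "+")
        assert extract_upstream(gene, seq).window_length == 0


# ---------------------------------------------------------------------------
# PWM arithmetic
# ---------------------------------------------------------------------------

class TestBuildPwm:
    def test_point_mass_without_pseudocount(self):
        pwm = build_pwm(["TGTCACA"] * 5, pseudocount=0.0)
        assert consensus(pwm) == "TGTCACA"
        assert np.allclose(pwm.max(axis=1), 1.0)

    def test_two_site_half_split(self):
        pwm = build_pwm(["AAAA", "CCCC"], pseudocount=0.0)
        assert np.allclose(pwm[:, 0], 0.5) and np.allclose(pwm[:, 1], 0.5)

    def test_single_site_pseudocount_formula(self):
        # (count + pc*bg) / (n + pc) with n=1, pc=1, bg=0.25
        pwm = build_pwm(["A"], pseudocount=1.0)
        assert pwm[0, 0] == pytest.approx((1 + 0.25) / 2)  # 0.625
        assert pwm[0, 1] == pytest.approx(0.25 / 2)

    def test_ragged_or_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            build_pwm(["ACGT", "ACG"])
        with pytest.raises(ValueError):
            build_pwm(["ACGN"])


class TestInformationContent:
    def test_point_mass_is_two_bits(self):
        pwm = np.array([[1.0, 0, 0, 0]])
        assert information_content(pwm)[0] == pytest.approx(2.0)

    def test_background_column_is_zero_bits(self):
        pwm = np.full((1, 4), 0.25)
        assert information_content(pwm)[0] == pytest.approx(0.0)

    def test_half_split_is_one_bit(self):
        pwm = np.array([[0.5, 0.5, 0, 0]])
        assert information_content(pwm)[0] == pytest.approx(1.0)


class TestConsensus:
    def test_half_split_gives_iupac_r(self):
        pwm = np.array([[0.5, 0.0, 0.5, 0.0]])
        assert consensus(pwm) == "R"

    def test_printed_minus35_heptamers_give_tgtcaca(self, blich_promoters):
        pwm = build_pwm([c.minus35 for c in blich_promoters])
        assert consensus(pwm) == "TGTCACA"


# ---------------------------------------------------------------------------
# scanning vs. a brute-force oracle
# ---------------------------------------------------------------------------

from oracles import oracle_scan as _oracle_scan
from oracles import random_seq as _random_seq


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("mutation_rate, threshold", [(0.0, 0.9), (0.05, 0.8)])
def test_scan_matches_bruteforce_enumeration(seed, mutation_rate, threshold):
    rng = np.random.default_rng(seed)
    model = generator_motif_model(mutation_rate=mutation_rate)
    seq = _random_seq(rng, 3000)
    # plant a couple of sites so the comparison includes real hits
    for pos in (500, 1600):
        text, spacer = (
            plant_site(seq[pos : pos + 40], model, rng)[0],
            None,
        )
        seq = seq[:pos] + text + seq[pos + 40 :]
    hits = scan(model, seq, "r", threshold=threshold)
    got = {(h.strand, h.start, h.end, h.spacer) for h in hits}
    assert got == _oracle_scan(model, seq, threshold)


@settings(max_examples=15, deadline=None)
@given(st.integers(0, 10_000))
def test_scan_matches_oracle_on_short_random_sequence(seed):
    rng = np.random.default_rng(seed)
    model = generator_motif_model(mutation_rate=0.1)
    seq = _random_seq(rng, 400, gc=0.4)
    hits = scan(model, seq, "r", threshold=0.75)
    got = {(h.strand, h.start, h.end, h.spacer) for h in hits}
    assert got == _oracle_scan(model, seq, 0.75)


def test_scan_reverse_complement_mirrors_hits():
    rng = np.random.default_rng(3)
    model = generator_motif_model(mutation_rate=0.05)
    seq = _random_seq(rng, 2000)
    w, _ = plant_site(seq[700:740], model, rng)
    seq = seq[:700] + w + seq[740:]
    fwd = scan(model, seq, "r", threshold=0.8)
    rev = scan(model, reverse_complement(seq), "r", threshold=0.8)
    n = len(seq)
    mirrored = {
        ("-" if h.strand == "+" else "+", n - h.end + 1, n - h.start + 1, h.spacer)
        for h in rev
    }
    assert {(h.strand, h.start, h.end, h.spacer) for h in fwd} == mirrored


def test_exact_consensus_is_the_only_hit_at_high_threshold():
    rng = np.random.default_rng(4)
    seq = _random_seq(rng, 1000)
    site = "TGTCACA" + _random_seq(rng, 16) + "CGTC"
    seq = seq[:400] + site + seq[400 + len(site):]
    model = generator_motif_model(mutation_rate=0.05)
    hits = scan(model, seq, "r", threshold=0.9)
    assert [(h.strand, h.start, h.spacer) for h in hits] == [("+", 401, 16)]


def test_poly_a_sequence_has_no_hits():
    model = generator_motif_model(mutation_rate=0.05)
    assert scan(model, "A" * 2000, "r", threshold=0.8) == []


def test_sequence_shorter_than_site_span_yields_nothing():
    model = generator_motif_model()
    assert scan(model, "ACGTACGT", "r") == []


def test_ambiguity_characters_score_as_background():
    model = generator_motif_model(mutation_rate=0.05)
    clean = "TGTCACA" + "A" * 16 + "CGTC"
    with_n = "TGTCACN" + "A" * 16 + "CGTC"  # N in the last -35 column
    (h1,) = scan(model, clean, "r", threshold=0.5, both_strands=False)
    (h2,) = scan(model, with_n, "r", threshold=0.5, both_strands=False)
    # N contributes zero log odds, i.e. the consensus column's contribution
    # is exactly what goes missing
    col7 = math.log2(model.pwm35[6, 0] / model.background[0])  # A at position 7
    assert h1.score - h2.score == pytest.approx(col7)


# ---------------------------------------------------------------------------
# discovery
# ---------------------------------------------------------------------------

def _windows_with_sites(seed, n=50, mutation_rate=0.0):
    rng = np.random.default_rng(seed)
    model = generator_motif_model(mutation_rate=mutation_rate)
    windows, records = [], []
    for _ in range(n):
        w = _random_seq(rng, 250)
        w2, rec = plant_site(w, model, rng)
        windows.append(w2)
        records.append(rec)
    return windows, records


def test_discovery_recovers_noiseless_planted_motif_exactly():
    windows, records = _windows_with_sites(seed=5)
    model, placements, info = discover_bipartite_motif(windows)
    assert model.consensus35() == "TGTCACA"
    assert model.consensus10() == "CGTC"
    assert not info["low_information"]
    # every placement coincides with the planted site
    for (wi, pos, spacer), rec in zip(placements, records):
        assert (pos, spacer) == (rec["pos"], rec["spacer"])
    planted = sorted(r["spacer"] for r in records)
    assert sorted(p[2] for p in placements) == planted


def test_discovery_recovers_consensus_in_19_of_20_noisy_datasets():
    recovered = 0
    for seed in range(20):
        windows, _ = _windows_with_sites(seed=1000 + seed, mutation_rate=0.05)
        model, _, _ = discover_bipartite_motif(windows)
        recovered += (
            model.consensus35() == "TGTCACA" and model.consensus10() == "CGTC"
        )
    assert recovered >= 19


def test_discovery_on_printed_candidates_aligns_at_position_one(blich_promoters):
    model, placements, info = discover_bipartite_motif(
        [c.sequence for c in blich_promoters]
    )
    assert all(pos == 1 for _, pos, _ in placements)
    assert model.consensus35().startswith("TGTCAC")
    assert not info["low_information"]


def test_discovery_flags_motif_free_sequence_as_low_information():
    rng = np.random.default_rng(6)
    windows = [_random_seq(rng, 250) for _ in range(30)]
    _, _, info = discover_bipartite_motif(windows)
    assert info["low_information"]


def test_discovery_rejects_too_few_or_too_short_windows():
    with pytest.raises(ValueError):
        discover_bipartite_motif(["ACGT" * 20] * 3)
    with pytest.raises(ValueError):
        discover_bipartite_motif(["ACGTACGTACGT"] * 10)


# ---------------------------------------------------------------------------
# spacer statistics and hit assignment
# ---------------------------------------------------------------------------

class TestSpacerStats:
    def test_printed_candidates_median_16(self, blich_promoters):
        stats = spacer_stats([c.spacer for c in blich_promoters])
        assert stats["median"] == 16
        assert stats["min"] >= 15 and stats["max"] <= 17

    def test_constant_spacers(self):
        stats = spacer_stats([16] * 7)
        assert stats["counts"] == {16: 7} and stats["median"] == 16

    def test_one_of_each(self):
        stats = spacer_stats([15, 16, 17])
        assert stats["median"] == 16 and (stats["min"], stats["max"]) == (15, 17)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            spacer_stats([])


class TestAssignHits:
    def _site(self, start, end, strand="+"):
        from ecf41.promoter_model import PromoterSite

        return PromoterSite(
            replicon_id="r", strand=strand, start=start, end=end,
            minus35_start=start if strand == "+" else end,
            spacer=16, score=20.0, relative_score=0.95, site_sequence="",
        )

    def test_hit_upstream_of_plus_gene_assigned_with_utr(self):
        gene = GeneRecord("g", "r", 1000, 1600, "+")
        hit = self._site(920, 946)  # ends 40 bp before the gene (plus 13)
        (out,) = assign_hits([hit], [gene])
        assert out.target_gene_id == "g"
        assert out.utr_proxy == 1000 - 946 - 1

    def test_hit_on_wrong_strand_not_assigned(self):
        gene = GeneRecord("g", "r", 1000, 1600, "-")
        (out,) = assign_hits([self._site(920, 946, "+")], [gene])
        assert out.target_gene_id is None

    def test_hit_inside_coding_region_not_assigned(self):
        gene = GeneRecord("g", "r", 1000, 1600, "+")
        (out,) = assign_hits([self._site(1200, 1226)], [gene])
        assert out.target_gene_id is None and out.utr_proxy is None

    def test_noiseless_synthetic_assignment_matches_truth(self, dataset_small):
        ds = dataset_small
        hits = []
        for rid, seq in ds.replicons.items():
            hits.extend(scan(ds.truth.generator_model, seq, rid, threshold=0.8))
        hits = assign_hits(hits, ds.genes)
        truth = {
            (s.replicon_id, s.strand, s.start): s.target_gene_id
            for s in ds.truth.sites
        }
        recovered = [
            h for h in hits if (h.replicon_id, h.strand, h.start) in truth
        ]
        assert len(recovered) == len(truth)
        assert all(
            truth[(h.replicon_id, h.strand, h.start)] == h.target_gene_id
            for h in recovered
        )


# ---------------------------------------------------------------------------
# model serialisation
# ---------------------------------------------------------------------------

def test_model_json_round_trip(tmp_path):
    model = generator_motif_model(mutation_rate=0.03)
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = BipartiteMotifModel.from_json(path)
    np.testing.assert_allclose(loaded.pwm35, model.pwm35)
    np.testing.assert_allclose(loaded.pwm10, model.pwm10)
    assert loaded.spacer_probs == model.spacer_probs


def test_meme_text_contains_both_motifs():
    text = generator_motif_model().to_meme()
    assert "MOTIF minus35" in text and "MOTIF minus10" in text
    assert "w= 7" in text and "w= 4" in text


def test_invalid_model_rejected():
    with pytest.raises(ValueError):
        BipartiteMotifModel(
            pwm35=np.full((7, 4), 0.3), pwm10=np.full((4, 4), 0.25),
            spacer_probs={16: 1.0},
        )
    with pytest.raises(ValueError):
        BipartiteMotifModel(
            pwm35=np.full((7, 4), 0.25), pwm10=np.full((4, 4), 0.25),
            spacer_probs={15: 0.5, 16: 0.2},
        )
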