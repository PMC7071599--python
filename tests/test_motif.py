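import numpy as np
import pytest

from sagescape import synthetic_data as sim
from sagescape.motif import (
    MotifPWM,
    background_frequencies,
    enrichment_report,
    randomization_p,
    read_jaspar,
    sequence_score,
    set_raw_score,
    site_calls,
    write_jaspar,
)
from sagescape.synthetic_data import reverse_complement


def uniform_pwm(width=6):
    return MotifPWM("MA9999.1", "UNIFORM", np.full((width, 4), 0.25), 0.0)


def strong_pwm():
    """High-information 10-mer (consensus ACGTACGTAC)."""
    counts = np.zeros((10, 4))
    for i, b in enumerate("ACGTACGTAC"):
        counts[i, "ACGT".index(b)] = 50
    return MotifPWM.from_counts("MA0001.1", "STRONG", counts, 0.375)


class TestJasparIO:
    def test_equal_counts_give_quarter_probs(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">MA0001.1 TEST\nA [ 5 5 ]\nC [ 5 5 ]\nG [ 5 5 ]\nT [ 5 5 ]\n")
        (m,) = read_jaspar(p, pseudocount=0.0)
        assert np.allclose(m.probs, 0.25)

    def test_pure_counts_without_pseudocount(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">MA0002.1 T2\nA [ 10 10 ]\nC [ 0 0 ]\nG [ 0 0 ]\nT [ 0 0 ]\n")
        (m,) = read_jaspar(p, pseudocount=0.0)
        assert np.allclose(m.probs[:, 0], 1.0)

    def test_pseudocount_softens(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">MA0002.1 T2\nA [ 10 ]\nC [ 0 ]\nG [ 0 ]\nT [ 0 ]\n")
        (m,) = read_jaspar(p, pseudocount=0.375)
        assert m.probs[0, 0] == pytest.approx(10.375 / 11.5)

    def test_ragged_rows_error_names_motif(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">MA0003.1 BAD\nA [ 1 2 3 ]\nC [ 1 2 ]\nG [ 1 2 3 ]\nT [ 1 2 3 ]\n")
        with pytest.raises(ValueError, match="MA0003.1"):
            read_jaspar(p)

    def test_roundtrip_preserves_probabilities(self, tmp_path):
        rng = np.random.default_rng(4)
        probs = rng.dirichlet(np.ones(4), size=7)
        m = MotifPWM("MA0004.1", "RT", probs, 0.0)
        p = tmp_path / "rt.jaspar"
        write_jaspar([m], p)
        (back,) = read_jaspar(p, pseudocount=0.0)
        assert np.allclose(back.probs, probs, atol=1e-9)
        assert back.id == "MA0004.1" and back.name == "RT"

    def test_multiple_motifs(self, tmp_path):
        p = tmp_path / "m.jaspar"
        write_jaspar([uniform_pwm(), strong_pwm()], p)
        motifs = read_jaspar(p, pseudocount=0.0)
        assert [m.id for m in motifs] == ["MA9999.1", "MA0001.1"]


class TestSequenceScore:
    def test_uniform_identity(self):
        avg, lrs = sequence_score("ACGTACGTAGGT", uniform_pwm())
        assert avg == pytest.approx(1.0)
        assert np.allclose(lrs, 1.0)

    def test_single_position_brute_force(self):
        # one-position A-only motif on "AAAA": forward LRs all 4; reverse
        # strand reads T -> LR 0; hand-computed mean = (4*4 + 4*0)/8
        pwm = MotifPWM("M", "A1", np.array([[1.0, 0.0, 0.0, 0.0]]), 0.0)
        avg, lrs = sequence_score("AAAA", pwm)
        assert len(lrs) == 8
        assert avg == pytest.approx((4 * 4.0 + 0.0) / 8)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(9)
        pwm = MotifPWM("M", "R", rng.dirichlet(np.ones(4), size=5), 0.0)
        seq = "ACGGTTACGTAGCATGCAAT"
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        a1, _ = sequence_score(seq, pwm, bg)
        a2, _ = sequence_score(reverse_complement(seq), pwm, bg)
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_n_positions_neutral(self):
        pwm = MotifPWM("M", "A1", np.array([[1.0, 0.0, 0.0, 0.0]]), 0.0)
        avg, lrs = sequence_score("NN", pwm)
        assert np.allclose(lrs, 1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sequence_score("ACG", uniform_pwm(6))

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValueError):
            sequence_score("ACGTACGT", uniform_pwm(), np.array([0.5, 0.5, 0.0, 0.0]))


class TestRawScore:
    def test_uniform_pwm_scores_zero(self):
        seqs = ["ACGTACGTAC", "TTTTGGGGCC", "CATGCATGCA"]
        assert set_raw_score(seqs, uniform_pwm()) == pytest.approx(0.0, abs=1e-12)

    def test_single_sequence(self):
        pwm = strong_pwm()
        seq = "TT" + "ACGTACGTAC" + "GG"
        avg, _ = sequence_score(seq, pwm)
        assert set_raw_score([seq], pwm) == pytest.approx(np.log(avg))

    def test_planted_beats_unplanted(self):
        # [DERIVED] paired simulation over seeds: planted foreground scores higher
        pwm = strong_pwm()
        wins = 0
        for seed in range(30):
            fore, back, _ = sim.simulate_promoters(
                8, 8, pwm, plant_rate=1.0, length=120, seed=seed
            )
            s_fore = set_raw_score([s for _, s in fore], pwm)
            s_back = set_raw_score([s for _, s in back], pwm)
            wins += s_fore > s_back
        assert wins == 30

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            set_raw_score([], uniform_pwm())


class TestRandomizationP:
    def test_null_p_moderate(self):
        # [DERIVED] null calibration: mean p over seeded runs in [0.3, 0.7]
        pwm = strong_pwm()
        rng = np.random.default_rng(77)
        pool = [sim._random_seq(rng, 150, 0.45) for _ in range(40)]
        ps = []
        for seed in range(50):
            r = np.random.default_rng(1000 + seed)
            idx = r.choice(len(pool), size=8, replace=False)
            fore = [pool[i] for i in idx]
            p, _ = randomization_p(fore, pwm, pool, n_rand=49, seed=seed)
            ps.append(p)
        assert 0.3 <= np.mean(ps) <= 0.7

    def test_strongly_planted_hits_minimum(self):
        pwm = strong_pwm()
        fore, back, _ = sim.simulate_promoters(20, 60, pwm, plant_rate=1.0, length=150, seed=3)
        p, _ = randomization_p(
            [s for _, s in fore], pwm, [s for _, s in back], n_rand=99, seed=4
        )
        assert p == pytest.approx(1.0 / 100.0)

    def test_bounds(self):
        pwm = strong_pwm()
        fore, back, _ = sim.simulate_promoters(5, 20, pwm, plant_rate=0.5, length=80, seed=5)
        for strategy in ("draw_matched_background", "shuffle_mononucleotide"):
            p, _ = randomization_p(
                [s for _, s in fore], pwm, [s for _, s in back],
                n_rand=19, strategy=strategy, seed=6,
            )
            assert 1.0 / 20.0 <= p <= 1.0

    def test_small_n_rand_rejected(self):
        with pytest.raises(ValueError, match="19"):
            randomization_p(["ACGTACGTACGT"], strong_pwm(), ["ACGTACGTACGT"], n_rand=10)

    def test_pool_smaller_than_foreground_rejected(self):
        seqs = ["ACGTACGTACGT"] * 3
        with pytest.raises(ValueError, match="pool"):
            randomization_p(seqs, strong_pwm(), seqs[:2], n_rand=20)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            randomization_p(["ACGTACGTACGT"], strong_pwm(), ["ACGTACGTACGT"] * 2,
                            n_rand=20, strategy="bogus")


class TestSiteCalls:
    def test_no_sites(self):
        occ, genes = site_calls(["TTTTTTTTTTTTTT"], strong_pwm())
        assert (occ, genes) == (0, 0)

    def test_one_planted_site_per_sequence(self):
        # [DERIVED] construction: consensus site in each of 10 sequences
        pwm = strong_pwm()
        rng = np.random.default_rng(8)
        seqs = []
        for _ in range(10):
            s = list("T" * 60)
            off = int(rng.integers(0, 50))
            s[off : off + 10] = "ACGTACGTAC"
            seqs.append("".join(s))
        occ, genes = site_calls(seqs, pwm)
        assert genes == 10
        assert occ >= 10

    def test_occurrence_at_least_gene_count(self):
        pwm = strong_pwm()
        fore, _, _ = sim.simulate_promoters(15, 0, pwm, plant_rate=0.7, length=100, seed=9)
        occ, genes = site_calls([s for _, s in fore], pwm)
        assert occ >= genes

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            site_calls(["ACGT"], uniform_pwm(4), lr_threshold=0.0)


class TestEnrichmentReport:
    def test_planted_motif_ranked_first(self):
        # [DERIVED] planted recovery among decoys
        pwm = strong_pwm()
        rng = np.random.default_rng(12)
        decoys = [
            MotifPWM(f"MA{i:04d}.1", f"DECOY{i}", rng.dirichlet(np.ones(4) * 2, size=8), 0.0)
            for i in range(5)
        ]
        fore, back, _ = sim.simulate_promoters(30, 90, pwm, plant_rate=0.8, length=200, seed=13)
        rep = enrichment_report(
            {"c1": [s for _, s in fore]}, [pwm] + decoys, [s for _, s in back],
            n_rand=199, seed=14,
        )
        top = rep.iloc[0]
        assert top["jaspar_id"] == "MA0001.1"
        assert top["fdr"] <= 0.05
        assert bool(top["significant"])

    def test_alpha_zero_nothing_significant(self):
        pwm = strong_pwm()
        fore, back, _ = sim.simulate_promoters(10, 30, pwm, plant_rate=1.0, length=100, seed=15)
        rep = enrichment_report(
            {"c1": [s for _, s in fore]}, [pwm], [s for _, s in back],
            alpha=0.0, n_rand=49, seed=16,
        )
        assert not rep["significant"].any()

    def test_schema_matches_report_table(self):
        pwm = strong_pwm()
        fore, back, _ = sim.simulate_promoters(5, 15, pwm, plant_rate=0.5, length=80, seed=17)
        rep = enrichment_report(
            {"c1": [s for _, s in fore]}, [pwm], [s for _, s in back], n_rand=49, seed=18
        )
        assert list(rep.columns) == [
            "cluster", "jaspar_id", "tf_name", "occurrence", "gene_count",
            "raw_score", "p", "fdr", "significant",
        ]

    def test_empty_cluster_skipped_with_warning(self):
        pwm = strong_pwm()
        fore, back, _ = sim.simulate_promoters(5, 15, pwm, plant_rate=0.5, length=80, seed=19)
        with pytest.warns(UserWarning, match="empty"):
            rep = enrichment_report(
                {"empty": [], "c1": [s for _, s in fore]}, [pwm], [s for _, s in back],
                n_rand=49, seed=20,
            )
        assert set(rep["cluster"]) == {"c1"}

    def test_p_never_zero(self):
        pwm = strong_pwm()
        fore, back, _ = sim.simulate_promoters(15, 45, pwm, plant_rate=1.0, length=120, seed=21)
        rep = enrichment_report(
            {"c1": [s for _, s in fore]}, [pwm], [s for _, s in back], n_rand=99, seed=22
        )
        assert (rep["p"] >= 1.0 / 100.0).all()


def test_background_frequencies():
    freqs = background_frequencies(["AACC", "GGTT"])
    assert np.allclose(freqs, 0.25)
    with pytest.raises(ValueError):
        background_frequencies(["NNN"])


def test_planted_motif_power():
    """plant_rate >= 0.5, 30 seqs, IC >= 10 bits -> fdr <= 0.05 in >= 95% of trials."""
    pwm = strong_pwm()
    assert pwm.information_content() >= 10
    hits = 0
    n_trials = 10
    for seed in range(n_trials):
        fore, back, _ = sim.simulate_promoters(30, 60, pwm, plant_rate=0.5, length=150, seed=seed)
        rep = enrichment_report(
            {"c": [s for _, s in fore]}, [pwm], [s for _, s in back], n_rand=99, seed=seed
        )
        hits += rep["fdr"].iloc[0] <= 0.05
    assert hits >= 0.95 * n_trials
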