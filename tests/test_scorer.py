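import numpy as np
import pytest

from cpgrank.datamodel import CpGSite, PredictionRecord
from cpgrank.scorer import (
    assemble_records,
    compute_lrs,
    enumerate_cpgs,
    score_genome,
    select_detached_loci,
)


class TestEnumerate:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACGTCG", [1, 4]),
            ("CGN", [0]),
            ("cg", [0]),          # soft-masked bases count
            ("CNG", []),          # N breaks the dinucleotide
            ("CCGG", [1]),
            ("AT", []),
        ],
    )
    def test_forward_strand_scan(self, seq, expected):
        sites = enumerate_cpgs(sequences={"chr1": seq})
        assert [s.pos for s in sites] == expected

    def test_deterministic_chrom_then_pos_order(self):
        sites = enumerate_cpgs(sequences={"chr2": "CGCG", "chr1": "ACG"})
        assert [(s.chrom, s.pos) for s in sites] == [("chr1", 1), ("chr2", 0), ("chr2", 2)]

    def test_empty_fasta_rejected(self):
        with pytest.raises(ValueError):
            enumerate_cpgs(sequences={"chr1": ""})

    def test_fasta_file_matches_in_memory(self, tmp_path, small_study):
        from cpgrank.io import write_fasta

        sequences = small_study[0]
        path = tmp_path / "g.fa"
        write_fasta(sequences, path)
        from_file = enumerate_cpgs(path)
        in_mem = enumerate_cpgs(sequences=sequences)
        assert [(s.chrom, s.pos) for s in from_file] == [(s.chrom, s.pos) for s in in_mem]
        # every enumerated site is a real CG in the genome
        from cpgrank.datamodel import validate_sites_against_genome

        validate_sites_against_genome(in_mem[:50], {c: s for c, s in sequences.items()})


class TestLrs:
    def test_rank_is_recovered_exactly_from_empirical_p(self):
        scores = np.linspace(1, 0, 50)
        ranks, lrs, emp = compute_lrs(scores)
        assert np.array_equal(np.round(emp * 50).astype(int), ranks)

    def test_lrs_strictly_decreasing_in_rank(self):
        scores = np.random.default_rng(0).uniform(size=100)
        ranks, lrs, _ = compute_lrs(scores)
        order = np.argsort(ranks)
        distinct = np.diff(ranks[order]) > 0
        assert np.all(np.diff(lrs[order])[distinct] < 0)

    def test_ties_share_best_rank_and_lrs(self):
        scores = np.array([0.9, 0.7, 0.7, 0.1])
        ranks, lrs, _ = compute_lrs(scores)
        assert list(ranks) == [1, 2, 2, 4]
        assert lrs[1] == lrs[2]

    def test_worst_rank_has_zero_lrs(self):
        ranks, lrs, emp = compute_lrs(np.array([0.3, 0.2, 0.1]))
        assert lrs[-1] == 0.0
        assert emp[-1] == 1.0

    def test_percentile_interpretation(self):
        # LRS 1 <-> rank/total = 0.1 (90th percentile), LRS 2 <-> 0.01
        scores = np.linspace(1, 0, 1000)
        ranks, lrs, _ = compute_lrs(scores)
        assert lrs[ranks == 100][0] == pytest.approx(1.0)
        assert lrs[ranks == 10][0] == pytest.approx(2.0)


class TestScoreGenome:
    def test_chunking_invariance(self, small_fit):
        run = small_fit
        sites = run.sites[:60]
        a = score_genome(run.fit.ensemble, sites, run.store, chunk_size=1)
        b = score_genome(run.fit.ensemble, sites, run.store, chunk_size=60)
        assert np.allclose(a, b, atol=1e-12)

    def test_training_positives_outscore_training_negatives(self, small_fit):
        run = small_fit
        by_id = {r.site_id: r for r in run.records}
        pos = np.mean([by_id[s].score["pathology"] for s in run.training_set.positives])
        neg = np.mean([by_id[s].score["pathology"] for s in run.training_set.negatives])
        assert pos > neg

    def test_uncovered_bin_imputed_with_warning(self, small_fit):
        run = small_fit
        ghost = [CpGSite("chrZ", 10)]
        with pytest.warns(UserWarning, match="uncovered"):
            scores = score_genome(run.fit.ensemble, ghost, run.store)
        assert 0 <= scores[0] <= 1

    def test_off_array_causal_sites_rank_high(self, planted_runs):
        """Truly associated CpGs never seen by the EWAS (off-array) should
        land in the top decile of genome-wide scores."""
        fractions = []
        for run in planted_runs.values():
            causal = set(run.truth.causal_sites["pathology"])
            on_array = {s.site_id for s in run.sites if s.on_array}
            off_causal = causal - on_array
            ranks, _, _ = compute_lrs(
                np.array([r.score["pathology"] for r in run.records])
            )
            by_id = dict(zip((r.site_id for r in run.records), ranks))
            decile = len(run.records) / 10
            frac = np.mean([by_id[s] <= decile for s in off_causal])
            fractions.append(frac)
        assert np.mean(fractions) >= 0.8


def _rec(chrom, pos, composite):
    return PredictionRecord(f"{chrom}:{pos}", chrom, pos, composite=composite)


class TestDetachedLoci:
    def test_exclusion_window_drops_nearby_lower_score(self):
        records = [_rec("chr1", 0, 3.0), _rec("chr1", 5000, 2.0), _rec("chr1", 20_000, 1.0)]
        sel = select_detached_loci(records, spacing_bp=10_000, k=3)
        assert sel.site_ids == ["chr1:0", "chr1:20000"]

    def test_zero_spacing_degenerates_to_top_k(self):
        records = [_rec("chr1", i, s) for i, s in enumerate([0.5, 2.0, 1.0])]
        sel = select_detached_loci(records, spacing_bp=0, k=2)
        assert sel.site_ids == ["chr1:1", "chr1:2"]

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            select_detached_loci([_rec("chr1", 0, 1.0)], 100, 0)

    def test_chromosomes_do_not_interfere(self):
        records = [_rec("chr1", 0, 3.0), _rec("chr2", 100, 2.5)]
        sel = select_detached_loci(records, spacing_bp=10_000, k=2)
        assert sel.site_ids == ["chr1:0", "chr2:100"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_oracle_on_small_instances(self, seed):
        """The greedy result must be the feasible subset that is
        lexicographically greatest in descending composite order."""
        from itertools import combinations

        rng = np.random.default_rng(seed)
        n = 8
        records = [
            _rec("chr1", int(p), float(s))
            for p, s in zip(rng.choice(10_000, n, replace=False), rng.uniform(0, 5, n))
        ]
        spacing, k = 2000, 3
        sel = select_detached_loci(records, spacing, k)

        def feasible(subset):
            return all(
                abs(a.pos - b.pos) >= spacing for a, b in combinations(subset, 2)
            )

        best_key = None
        m = len(sel.site_ids)
        for combo in combinations(records, m):
            if feasible(combo):
                key = tuple(sorted((-r.composite for r in combo)))
                if best_key is None or key < best_key:
                    best_key = key
        got_key = tuple(
            sorted(-r.composite for r in records if r.site_id in set(sel.site_ids))
        )
        assert got_key == best_key


class TestAssembleRecords:
    def test_composite_is_sum_of_trait_lrs(self):
        sites = [CpGSite("chr1", 0), CpGSite("chr1", 10)]
        scores = {"a": np.array([0.9, 0.1]), "b": np.array([0.2, 0.8])}
        records = assemble_records(sites, scores)
        for r in records:
            assert r.composite == pytest.approx(sum(r.lrs.values()))

    def test_mean_and_max_rules(self):
        sites = [CpGSite("chr1", 0), CpGSite("chr1", 10)]
        scores = {"a": np.array([0.9, 0.1]), "b": np.array([0.2, 0.8])}
        mean_r = assemble_records(sites, scores, composite="mean")
        max_r = assemble_records(sites, scores, composite="max")
        for rm, rx in zip(mean_r, max_r):
            assert rm.composite == pytest.approx(np.mean(list(rm.lrs.values())))
            assert rx.composite == pytest.approx(max(rx.lrs.values()))
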