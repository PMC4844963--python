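"""Target prediction: top-hit selection, Mann-Whitney, signature scan, repeats."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pirnadev import targets as tg
from pirnadev.model import GeneModel, RepeatElement, reverse_complement


class TestTopGeneTargets:
    def _hits(self, rows):
        return pd.DataFrame(rows, columns=["pirna_id", "gene_id", "score"])

    def test_top_scoring_above_threshold(self):
        hits = self._hits([("p1", "gA", 150), ("p1", "gB", 165), ("p1", "gC", 170)])
        out = tg.select_top_gene_targets(hits)
        assert out.iloc[0]["gene_id"] == "gC"

    def test_all_below_threshold_no_target(self):
        hits = self._hits([("p1", "gA", 150), ("p1", "gB", 159)])
        assert len(tg.select_top_gene_targets(hits)) == 0

    def test_tie_broken_lexicographically(self):
        hits = self._hits([("p1", "gB", 170), ("p1", "gA", 170)])
        assert tg.select_top_gene_targets(hits).iloc[0]["gene_id"] == "gA"

    def test_expressed_gene_restriction(self):
        hits = self._hits([("p1", "gA", 200), ("p1", "gB", 180)])
        out = tg.select_top_gene_targets(hits, expressed_genes={"gB"})
        assert out.iloc[0]["gene_id"] == "gB"


def mw_enumeration_oracle(x, y):
    """Two-sided exact p by full enumeration over all labelings (no ties)."""
    x, y = list(x), list(y)
    n1 = len(x)
    combined = x + y
    ranks = stats.rankdata(combined)
    U_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    n1n2 = n1 * len(y)
    lo = min(U_obs, n1n2 - U_obs)
    hits = total = 0
    all_ranks = list(range(1, len(combined) + 1))
    for subset in itertools.combinations(all_ranks, n1):
        u = sum(subset) - n1 * (n1 + 1) / 2
        total += 1
        hits += min(u, n1n2 - u) <= lo + 1e-9
    return U_obs, hits / total


class TestMannWhitney:
    def test_separated_groups_exact(self):
        U, p = tg.mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 0.0 and p == pytest.approx(0.10)

    def test_identical_single_values_midranks(self):
        U, p = tg.mann_whitney([5.0], [5.0])
        assert U == 0.5 and p == 1.0

    @pytest.mark.parametrize("n1, n2", [(2, 3), (3, 3), (4, 4), (5, 5), (6, 6), (3, 9)])
    def test_exact_matches_enumeration(self, n1, n2, rng):
        for _ in range(5):
            data = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = data[:n1], data[n1:]
            U, p = tg.mann_whitney(x, y)
            U_oracle, p_oracle = mw_enumeration_oracle(x, y)
            assert U == pytest.approx(U_oracle)
            assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_large_symmetric_u_near_center(self, rng):
        x = rng.normal(size=300)
        y = rng.normal(size=300)
        U, p = tg.mann_whitney(x, y)
        mean = 300 * 300 / 2
        sd = np.sqrt(300 * 300 * 601 / 12)
        assert abs(U - mean) < 3 * sd
        assert p > 0.001

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            tg.mann_whitney([], [1.0])


class TestDeadenylationTest:
    def test_zero_values_dropped_from_both_groups(self):
        res = tg.deadenylation_test(
            ["t1", "t2", "t3"],
            {"t1": 0.0, "t2": 0.0, "t3": -1.0, "n1": 0.0, "n2": 1.0},
        )
        assert res["n_targets"] == 1 and res["n_nontargets"] == 1
        assert res["median_target"] == -1.0 and res["median_nontarget"] == 1.0

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            tg.deadenylation_test(["t"], {"t": 0.0, "n": 0.0})

    def test_downregulated_targets_detected(self, rng):
        gfold = {}
        targets = []
        for i in range(200):
            targets.append(f"t{i}")
            gfold[f"t{i}"] = rng.normal(-1, 1)
            gfold[f"n{i}"] = rng.normal(+1, 1)
        res = tg.deadenylation_test(targets, gfold)
        assert res["p_value"] < 1e-6
        assert res["median_target"] < res["median_nontarget"]


# --------------------------------------------------------------- signature

def brute_force_guide_sites(guide, genome, seed_len=10, budget=160, phred=30):
    """Independent per-offset scan counting mismatches directly."""
    sites = []
    L = len(guide)
    for chrom, seq in genome.items():
        for strand in ("+", "-"):
            pattern = guide if strand == "+" else reverse_complement(guide)
            for off in range(len(seq) - L + 1):
                window = seq[off:off + L]
                mism_read_pos = []
                for j, (a, b) in enumerate(zip(pattern, window)):
                    if a != b:
                        mism_read_pos.append(j if strand == "+" else L - 1 - j)
                if any(p < seed_len for p in mism_read_pos):
                    continue
                if phred * len(mism_read_pos) <= budget:
                    sites.append((chrom, off, off + L, strand, tuple(sorted(mism_read_pos))))
    return sites


@pytest.fixture(scope="module")
def small_genome():
    rng = np.random.default_rng(77)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=20_000))}


class TestSignatureScan:
    def _plant(self, genome, pos, guide_len=26, mismatches=()):
        locus = genome["chr1"][pos:pos + guide_len]
        sense = locus
        guide = list(reverse_complement(locus))
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for p in mismatches:
            guide[p] = swap[guide[p]]
        return "".join(guide), sense

    def test_perfect_complement_site_emitted(self, small_genome):
        guide, sense = self._plant(small_genome, 5000)
        sites = tg.signature_scan({"g": guide}, {"s": sense}, small_genome)
        assert any(s.start == 5000 and s.guide_strand == "-" for s in sites)
        assert all(s.sense_ids for s in sites)

    def test_seed_mismatch_kills_guide_site(self, small_genome):
        guide, sense = self._plant(small_genome, 5000, mismatches=(5,))
        sites = tg.signature_scan({"g": guide}, {"s": sense}, small_genome)
        assert not any(s.start == 5000 for s in sites)

    @pytest.mark.parametrize("n_mm, expect_site", [(5, True), (6, False)])
    def test_quality_budget_five_vs_six_mismatches(self, small_genome, n_mm, expect_site):
        # at Q30, 5 non-seed mismatches cost 150 <= 160; 6 cost 180 > 160
        positions = tuple(range(12, 12 + n_mm))
        guide, sense = self._plant(small_genome, 8000, mismatches=positions)
        sites = tg.signature_scan({"g": guide}, {"s": sense}, small_genome)
        assert any(s.start == 8000 for s in sites) is expect_site

    def test_no_site_without_opposite_strand_sense(self, small_genome):
        guide, sense = self._plant(small_genome, 5000)
        # sense read matching the guide's own strand only (revcomp of locus)
        sites = tg.signature_scan({"g": guide},
                                  {"s": reverse_complement(sense)}, small_genome)
        same_locus = [s for s in sites if s.start == 5000]
        # the revcomp sense aligns - strand at the locus, same as the guide
        assert not same_locus

    def test_guide_shorter_than_seed_rejected(self, small_genome):
        with pytest.warns(UserWarning, match="shorter than seed"):
            sites = tg.signature_scan({"g": "ACGTACG"}, {"s": "ACGTACGTACGT"},
                                      small_genome)
        assert sites == []

    def test_matches_brute_force_oracle(self, small_genome, rng):
        guides = {}
        for i in range(4):
            pos = int(rng.integers(0, 19_000))
            guide, _ = self._plant(small_genome, pos,
                                   mismatches=tuple(rng.choice(range(10, 26), 3, replace=False)))
            guides[f"g{i}"] = guide
        for gid, guide in guides.items():
            expected = brute_force_guide_sites(guide, small_genome)
            observed = [
                (c, s, e, strand, mm)
                for c, s, e, strand, _, mm in tg.guide_sites({gid: guide}, small_genome)
            ]
            assert sorted(observed) == sorted(expected)

    def test_ping_pong_register_required_when_enabled(self, small_genome):
        guide, sense = self._plant(small_genome, 5000)
        # full 26-base overlap: not the 10-base 5'-5' register
        sites = tg.signature_scan({"g": guide}, {"s": sense}, small_genome,
                                  ping_pong=True)
        assert not any(s.start == 5000 for s in sites)
        # sense shifted so 5' ends overlap by exactly 10 bases
        shifted = small_genome["chr1"][5016:5042]
        sites = tg.signature_scan({"g": guide}, {"s": shifted}, small_genome,
                                  ping_pong=True)
        assert any(s.start == 5000 for s in sites)


class TestRepeatFilter:
    def _rep(self, length, consensus):
        return RepeatElement("chr1", 0, length, "+", "SINE", consensus)

    @pytest.mark.parametrize("length, kept", [(800, True), (750, True), (740, False)])
    def test_75_percent_boundary(self, length, kept):
        out, _ = tg.filter_repeats([self._rep(length, 1000)])
        assert (len(out) == 1) is kept

    def test_missing_consensus_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="consensus"):
            out, skipped = tg.filter_repeats([self._rep(500, 0)])
        assert out == [] and skipped == 1

    def test_monotone_in_min_fraction(self, rng):
        reps = [self._rep(int(rng.integers(100, 1200)), 1000) for _ in range(50)]
        kept_loose, _ = tg.filter_repeats(reps, min_fraction=0.5)
        kept_tight, _ = tg.filter_repeats(reps, min_fraction=0.9)
        assert set(id(r) for r in kept_tight) <= set(id(r) for r in kept_loose)


class TestAnnotateTargets:
    SITE_ARGS = dict(guide_id="g", guide_strand="-", sense_ids=("s",))

    def test_gene_repeat_and_unannotated(self):
        from pirnadev.model import TargetSignatureSite
        genes = [GeneModel("g1", "chr1", "+", 1000, 2000, (1000,))]
        reps = [RepeatElement("chr1", 5000, 5400, "+", "SINE", 400)]
        sites = [
            TargetSignatureSite("chr1", 1500, 1526, **self.SITE_ARGS),
            TargetSignatureSite("chr1", 1600, 1626, **self.SITE_ARGS),  # same gene
            TargetSignatureSite("chr1", 5390, 5416, **self.SITE_ARGS),  # SINE overlap
            TargetSignatureSite("chr1", 9000, 9026, **self.SITE_ARGS),  # nothing
        ]
        out = tg.annotate_targets(sites, genes, reps)
        assert out["mrna_targets"] == ["g1"]  # reported once despite two sites
        assert out["repeat_targets_by_family"] == {"SINE": 1}
        assert out["unannotated_sites"] == 1
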