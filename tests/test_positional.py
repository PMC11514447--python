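"""Occupancy, profiles, consensus clustering, motifs, overlap testing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from posclip.clip import BindingRegion
from posclip.positional import (
    compute_occupancy,
    consensus_cluster,
    kmer_enrichment,
    metagene_profile,
    overlap_randomization,
    select_motif_regions,
    stemloop_profile,
)
from posclip.transcriptome import REGIONS


def _sites(rows):
    return pd.DataFrame(rows, columns=["gene_id", "tx_pos", "count"])


class TestOccupancy:
    def test_counts_land_in_the_right_region(self, toy_models):
        # gA: utr5=200 -> 5'UTR region is [0,150)
        sites = _sites([("gA", p, 10) for p in range(0, 100, 10)])
        occ = compute_occupancy(sites, toy_models, ["gA"])
        assert occ["count_five_prime_utr"].iloc[0] == 100
        assert occ[[f"count_{r}" for r in REGIONS[1:]]].iloc[0].sum() == 0

    def test_rpkm_formula(self, toy_models):
        # 10 reads in the 5'UTR region; force library 1e6 for the check
        sites = _sites([("gA", 10, 10), ("gA", 400, 90)])
        occ = compute_occupancy(sites, toy_models, ["gA"], library_size=1e6)
        # 5'UTR region of gA is 150 nt: 10 / (0.150 * 1) = 66.67
        assert occ["rpkm_five_prime_utr"].iloc[0] == pytest.approx(10 / 0.150)

    def test_read_filter_is_strictly_greater_than(self, toy_models):
        sites = pd.concat([
            _sites([("gA", 5, 20)]),            # exactly 20: excluded
            _sites([("gB", 5, 21)]),            # 21: kept
        ])
        occ = compute_occupancy(sites, toy_models, ["gA", "gB"])
        assert list(occ["gene_id"]) == ["gB"]

    def test_counts_are_conserved(self, toy_models):
        rng = np.random.default_rng(3)
        rows = [("gC", int(p), int(c)) for p, c in
                zip(rng.integers(0, 380, 50), rng.integers(1, 9, 50))]
        sites = _sites(rows).groupby(["gene_id", "tx_pos"], as_index=False).sum()
        occ = compute_occupancy(sites, toy_models, ["gC"])
        total = occ[[f"count_{r}" for r in REGIONS]].iloc[0].sum()
        assert total == sites["count"].sum()

    def test_missing_model_raises(self, toy_models):
        with pytest.raises(KeyError):
            compute_occupancy(_sites([("gX", 1, 30)]), toy_models, ["gX"])


class TestMetagene:
    def test_point_mass_at_anchor_is_a_delta(self, toy_models):
        m = toy_models["gA"]
        sites = _sites([("gA", m.cds_start_tx, 50)])
        prof = metagene_profile(sites, {"gA": toy_models["gA"]}, anchor="start",
                                flank=100)
        assert prof.loc[prof["offset"] == 0, "density"].iloc[0] == pytest.approx(1.0)
        assert prof.loc[prof["offset"] != 0, "density"].sum() == 0

    def test_union_profile_is_gene_weighted_mean(self, toy_models):
        rng = np.random.default_rng(4)
        sA = _sites([("gA", int(p), 1) for p in rng.integers(0, 900, 40)])
        sB = _sites([("gB", int(p), 1) for p in rng.integers(0, 850, 40)])
        both = pd.concat([sA, sB], ignore_index=True)
        pA = metagene_profile(sA, {"gA": toy_models["gA"]}, "stop", 100)
        pB = metagene_profile(sB, {"gB": toy_models["gB"]}, "stop", 100)
        pU = metagene_profile(both, {k: toy_models[k] for k in ("gA", "gB")},
                              "stop", 100)
        num = (pA["density"] * pA["n"]).to_numpy() + \
              (pB["density"] * pB["n"]).to_numpy()
        den = (pA["n"] + pB["n"]).to_numpy()
        expected = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        assert np.allclose(pU["density"], expected)

    def test_bad_anchor_rejected(self, toy_models):
        with pytest.raises(ValueError):
            metagene_profile(_sites([]), toy_models, anchor="middle")


def _archetype_occupancy(rng, per_cluster=40, depth=500, noise=0.02):
    """One-hot-ish occupancy rows with small off-target counts."""
    rows = []
    for j, region in enumerate(REGIONS):
        for i in range(per_cluster):
            p = np.full(5, noise / 4)
            p[j] = 1 - noise
            counts = rng.multinomial(depth, p)
            rec = {"gene_id": f"{region}_{i}"}
            rec.update({f"count_{r}": int(c) for r, c in zip(REGIONS, counts)})
            rec.update({f"rpkm_{r}": float(c) for r, c in zip(REGIONS, counts)})
            rows.append(rec)
    return pd.DataFrame(rows)


class TestConsensusCluster:
    def test_clean_archetypes_fully_recovered(self):
        rng = np.random.default_rng(0)
        occ = _archetype_occupancy(rng, per_cluster=30, noise=0.0)
        assign, labels = consensus_cluster(occ, rounds=60, seed=1)
        assert sorted(labels.values()) == sorted(REGIONS)
        assert (assign["occurrence"] == 1.0).all()
        for row in assign.itertuples():
            assert row.gene_id.rsplit("_", 1)[0] == row.label

    def test_exactly_uniform_gene_is_unassigned(self):
        rng = np.random.default_rng(1)
        occ = _archetype_occupancy(rng, per_cluster=30, noise=0.0)
        plain = occ[["gene_id"] + [f"rpkm_{r}" for r in REGIONS]]
        probe = {"gene_id": "uniform_probe"}
        probe.update({f"rpkm_{r}": 0.2 for r in REGIONS})
        plain = pd.concat([plain, pd.DataFrame([probe])], ignore_index=True)
        assign, _ = consensus_cluster(plain, rounds=100, seed=2)
        row = assign[assign["gene_id"] == "uniform_probe"].iloc[0]
        assert row.label == "unassigned"
        assert row.occurrence < 0.70

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        occ = _archetype_occupancy(rng, per_cluster=15)
        a1, _ = consensus_cluster(occ, rounds=40, seed=3)
        shuffled = occ.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a2, _ = consensus_cluster(shuffled, rounds=40, seed=3)
        merged = a1.merge(a2, on="gene_id", suffixes=("_a", "_b"))
        agree = (merged["label_a"] == merged["label_b"]).mean()
        assert agree >= 0.98

    def test_row_scaling_invariance(self):
        rng = np.random.default_rng(3)
        occ = _archetype_occupancy(rng, per_cluster=15)
        plain = occ[["gene_id"] + [f"rpkm_{r}" for r in REGIONS]]
        scaled = plain.copy()
        for c in scaled.columns[1:]:
            scaled[c] = scaled[c] * 7.3
        a1, _ = consensus_cluster(plain, rounds=40, seed=4)
        a2, _ = consensus_cluster(scaled, rounds=40, seed=4)
        # correlation distance makes labels scale-free; occurrence can move
        # by floating-point differences in the resampling proportions
        assert list(a1["label"]) == list(a2["label"])
        assert np.allclose(a1["occurrence"], a2["occurrence"], atol=0.1)

    def test_fewer_genes_than_k_raises(self):
        rng = np.random.default_rng(4)
        occ = _archetype_occupancy(rng, per_cluster=15).head(3)
        with pytest.raises(ValueError):
            consensus_cluster(occ)


class TestStemloopProfile:
    def test_upstream_only_sites(self):
        sl = pd.DataFrame({"gene_id": ["h1"], "stemloop_start_tx": [500]})
        sites = _sites([("h1", 500 - d, 5) for d in range(1, 31)])
        prof, summary = stemloop_profile(sites, sl, window=100)
        assert summary["upstream_fraction"] == pytest.approx(1.0)
        assert -30 <= summary["peak_offset"] <= -1

    def test_uniform_sites_split_evenly(self):
        sl = pd.DataFrame({"gene_id": ["h1"], "stemloop_start_tx": [500]})
        sites = _sites([("h1", 500 + o, 1) for o in range(-100, 100)])
        _, summary = stemloop_profile(sites, sl, window=100)
        assert summary["upstream_fraction"] == pytest.approx(0.5)

    def test_gene_without_sites_contributes_zeros(self):
        sl = pd.DataFrame({"gene_id": ["h1", "h2"],
                           "stemloop_start_tx": [500, 400]})
        sites = _sites([("h1", 480, 10)])
        prof, summary = stemloop_profile(sites, sl, window=50)
        assert summary["n_genes"] == 2
        assert prof["density"].sum() == pytest.approx(0.5)  # h2 is all zeros
        with pytest.raises(ValueError):
            stemloop_profile(sites, sl.head(0))


class TestMotifSelection:
    def _enrichment(self):
        return pd.DataFrame({
            "gene_id": ["gE", "gN"],
            "status": ["enriched", "non_binder"],
        })

    def test_most_peaks_wins_and_flank_arithmetic(self):
        seqs = {"gE": "A" * 300, "gN": "C" * 300}
        regions = [
            BindingRegion("gE", 50, 70, n_peaks=3, read_count=100),
            BindingRegion("gE", 90, 110, n_peaks=5, read_count=40),
            BindingRegion("gN", 140, 160, n_peaks=1, read_count=25),
        ]
        targets, background = select_motif_regions(regions, self._enrichment(),
                                                   seqs)
        assert len(targets) == 1
        header, seq = targets[0]
        assert header == "gE:80-120"  # centre 100, 20 nt each side
        assert len(seq) == 40
        assert len(background) == 1 and background[0][0].startswith("gN")

    def test_background_requires_more_than_twenty_reads(self):
        seqs = {"gN": "C" * 300, "gE": "A" * 300}
        regions = [
            BindingRegion("gE", 90, 110, 2, 50),
            BindingRegion("gN", 40, 60, 1, 20),  # exactly 20: excluded
        ]
        _, background = select_motif_regions(regions, self._enrichment(), seqs)
        assert background == []

    def test_enriched_gene_without_region_is_skipped(self):
        targets, _ = select_motif_regions(
            [BindingRegion("gN", 40, 60, 1, 30)], self._enrichment(),
            {"gN": "C" * 100})
        assert targets == []


class TestKmerEnrichment:
    def test_planted_motif_ranks_first_with_closed_form_p(self):
        rng = np.random.default_rng(0)
        nt = np.array(list("ACGT"))
        def rs(n):
            return "".join(rng.choice(nt, n))
        motif = "TGCATG"
        targets = []
        for _ in range(50):
            s = rs(40)
            i = int(rng.integers(0, 34))
            targets.append(s[:i] + motif + s[i + 6:])
        background = []
        while len(background) < 70:
            s = rs(40)
            if motif not in s:
                background.append(s)
        hits = kmer_enrichment(targets, background)
        top = hits.iloc[0]
        assert top["kmer"] == motif
        assert top["p_adj"] < 1e-6
        # independent closed form: all 50 of 50 targets hit, 0 of 70 background
        expected = stats.hypergeom.sf(49, 120, 50, 50)
        assert top["p_value"] == pytest.approx(expected, rel=1e-9)

    def test_identical_sets_show_no_signal(self):
        rng = np.random.default_rng(1)
        nt = np.array(list("ACGT"))
        seqs = ["".join(rng.choice(nt, 40)) for _ in range(30)]
        hits = kmer_enrichment(seqs, seqs)
        assert (hits["target_frac"] == hits["background_frac"]).all()
        assert hits["p_adj"].min() > 0.05

    def test_short_sequences_skipped_per_size(self):
        hits = kmer_enrichment(["ACGTACGTAC"], ["TTTTTTTTTT", "ACG"],
                               sizes=(4, 8))
        assert set(hits["size"]) == {4, 8}
        # the 3-nt background sequence cannot contribute to either size
        assert (hits["background_frac"] <= 1.0).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kmer_enrichment([], ["ACGT"])


class TestOverlapRandomization:
    def test_observed_matches_bruteforce_intersection(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            q = [(int(s), int(s) + int(rng.integers(1, 20)))
                 for s in rng.integers(0, 300, 5)]
            r = [(int(s), int(s) + int(rng.integers(1, 20)))
                 for s in rng.integers(0, 300, 5)]
            res = overlap_randomization(q, r, [(0, 400)], n_samples=5, seed=0)
            qb = np.zeros(400, bool)
            rb = np.zeros(400, bool)
            for s, e in q:
                qb[s:e] = True
            for s, e in r:
                rb[s:e] = True
            assert res.observed_overlap == int((qb & rb).sum())

    def test_identical_query_and_reference(self):
        q = [(10, 60), (200, 260)]
        res = overlap_randomization(q, q, [(0, 100000)], n_samples=199, seed=1)
        assert res.p_empirical == pytest.approx(1 / 200)
        assert res.fold > 10
        assert res.observed_overlap == 110

    def test_empty_reference(self):
        res = overlap_randomization([(10, 20)], [], [(0, 1000)],
                                    n_samples=49, seed=0)
        assert res.observed_overlap == 0
        assert res.fold == 0.0
        assert res.p_empirical == 1.0

    def test_workspace_too_small_raises(self):
        with pytest.raises(ValueError):
            overlap_randomization([(0, 500)], [(0, 10)], [(0, 100)],
                                  n_samples=5, seed=0)
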