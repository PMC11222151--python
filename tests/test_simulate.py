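"""Synthetic-data generator: planted identities, implants, occupancy."""

import numpy as np
import pytest

from soilvirome import simulate
from soilvirome.simulate import SimConfig


def hamming_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


class TestMakeViralGenomes:
    def test_within_ani_100_gives_identical_members(self):
        cfg = SimConfig(seed=3, planted_clusters=[(2, 100.0, 85.0)])
        contigs, _ = simulate.make_viral_genomes(cfg)
        a, b = contigs.values()
        assert a == b

    def test_pairwise_member_identity_matches_plan(self):
        cfg = SimConfig(
            seed=5,
            genome_length_range=(10_000, 10_000),
            planted_clusters=[(2, 97.0, 85.0)],
        )
        contigs, _ = simulate.make_viral_genomes(cfg)
        a, b = contigs.values()
        assert hamming_identity(a, b) == pytest.approx(97.0, abs=0.5)

    def test_dtr_implant_copies_prefix_to_suffix(self):
        cfg = SimConfig(seed=7, planted_clusters=[(1, 99.0, 85.0)], dtr_length=20)
        contigs, _ = simulate.make_viral_genomes(cfg)
        (seq,) = contigs.values()
        assert seq[:20] == seq[-20:]

    def test_saturating_substitution_rate_rejected(self):
        with pytest.raises(ValueError, match="saturat"):
            SimConfig(seed=1, planted_clusters=[(2, 20.0, 10.0)])

    def test_within_must_exceed_between(self):
        with pytest.raises(ValueError, match="within_ani"):
            SimConfig(seed=1, planted_clusters=[(2, 85.0, 90.0)])

    def test_ground_truth_covers_every_genome_once(self):
        cfg = SimConfig(seed=9, planted_clusters=[(3, 97.0, 85.0), (2, 96.0, 80.0)])
        contigs, truth = simulate.make_viral_genomes(cfg)
        assert set(truth.cluster_of) == set(contigs)
        assert len(truth.cluster_of) == 5

    def test_within_cluster_identity_exceeds_between(self):
        cfg = SimConfig(
            seed=13,
            genome_length_range=(3_000, 3_000),
            planted_clusters=[(2, 97.0, 85.0), (2, 97.0, 85.0)],
        )
        contigs, truth = simulate.make_viral_genomes(cfg)
        ids = sorted(contigs)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                ident = hamming_identity(contigs[a], contigs[b])
                if truth.cluster_of[a] == truth.cluster_of[b]:
                    assert ident > 85.0
                else:
                    assert ident < 85.0

    def test_same_seed_is_byte_identical(self):
        cfg = SimConfig(seed=21)
        first, _ = simulate.make_viral_genomes(cfg)
        second, _ = simulate.make_viral_genomes(SimConfig(seed=21))
        assert first == second


class TestMakeGeneTable:
    def test_tiling_coordinates(self):
        contigs = {"c1": "A" * 3_000}
        genes = simulate.make_gene_table(
            contigs, {"c1": ["VV-1", "UNCLASSIFIED", "VV-1"]}, gene_length=900
        )
        assert [(g.start, g.end) for g in genes] == [(1, 900), (1001, 1900), (2001, 2900)]
        assert [g.strand for g in genes] == ["+", "-", "+"]

    def test_empty_layout(self):
        assert simulate.make_gene_table({"c1": "A" * 1000}, {"c1": []}) == []

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="capacity"):
            simulate.make_gene_table(
                {"c1": "A" * 3_000}, {"c1": ["VV-1"] * 4}, gene_length=900
            )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="marker label"):
            simulate.make_gene_table({"c1": "A" * 3_000}, {"c1": ["viral"]})


class TestMakeHostDb:
    def test_counts(self, small_cfg):
        db, lineages = simulate.make_host_db(3, 2, small_cfg)
        assert len(db.spacers) == 6
        assert len(lineages) == 3

    def test_fixed_spacer_length(self, small_cfg):
        small_cfg.spacer_length_range = (30, 30)
        db, _ = simulate.make_host_db(2, 3, small_cfg)
        assert all(len(s) == 30 for s in db.spacers.values())

    def test_hosts_sharing_genus_share_higher_ranks(self, small_cfg):
        _, lineages = simulate.make_host_db(4, 1, small_cfg, hosts_per_genus=2)
        l0, l1 = lineages.iloc[0], lineages.iloc[1]
        for rank in ("domain", "phylum", "class", "order", "family", "genus"):
            assert l0[rank] == l1[rank]
        assert l0["species"] != l1["species"]


class TestImplantProtospacers:
    def _setup(self, small_cfg):
        contigs, _ = simulate.make_viral_genomes(small_cfg)
        db, _ = simulate.make_host_db(2, 2, small_cfg)
        return contigs, db

    def test_exact_implant_verbatim(self, small_cfg):
        contigs, db = self._setup(small_cfg)
        cid = sorted(contigs)[0]
        sid = sorted(db.spacers)[0]
        out, truth = simulate.implant_protospacers(contigs, db, [(cid, sid, 0, "+", 100)])
        spacer = db.spacers[sid]
        assert out[cid][100 : 100 + len(spacer)] == spacer
        assert truth.implants[0].mismatches == 0

    def test_minus_strand_one_mismatch(self, small_cfg):
        contigs, db = self._setup(small_cfg)
        cid = sorted(contigs)[0]
        sid = sorted(db.spacers)[0]
        out, _ = simulate.implant_protospacers(
            contigs, db, [(cid, sid, 1, "-", 500)], seed=4
        )
        spacer = db.spacers[sid]
        window = out[cid][500 : 500 + len(spacer)]
        rc = simulate.reverse_complement(window)
        diffs = sum(a != b for a, b in zip(rc, spacer))
        assert diffs == 1

    def test_overlap_rejected(self, small_cfg):
        contigs, db = self._setup(small_cfg)
        cid = sorted(contigs)[0]
        s0, s1 = sorted(db.spacers)[:2]
        with pytest.raises(ValueError, match="overlap"):
            simulate.implant_protospacers(
                contigs, db, [(cid, s0, 0, "+", 100), (cid, s1, 0, "+", 110)]
            )

    def test_two_mismatch_plan_recorded(self, small_cfg):
        contigs, db = self._setup(small_cfg)
        cid = sorted(contigs)[0]
        sid = sorted(db.spacers)[0]
        _, truth = simulate.implant_protospacers(contigs, db, [(cid, sid, 2, "+", 900)])
        assert truth.implants[0].mismatches == 2


class TestMakeOccupancy:
    def test_degenerate_single_sample(self):
        m = simulate.make_occupancy(5, 50, abundance_model=("geometric", {"p": 1.0}), seed=2)
        assert ((m > 0).sum(axis=1) == 1).all()

    def test_all_ones(self):
        m = simulate.make_occupancy(4, 7, abundance_model=("ones", {}), seed=2)
        assert (m == 1).all().all()

    def test_geometric_tail_matches_closed_form(self):
        # P(attribute occupies >1 sample) = 1 - p for a geometric occupancy
        p, n = 0.9, 20_000
        m = simulate.make_occupancy(50, n, abundance_model=("geometric", {"p": p}), seed=3)
        frac = ((m > 0).sum(axis=1) > 1).mean()
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(frac - (1 - p)) <= 3 * sd

    def test_deterministic_given_seed(self):
        a = simulate.make_occupancy(10, 100, seed=5)
        b = simulate.make_occupancy(10, 100, seed=5)
        assert a.equals(b)
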