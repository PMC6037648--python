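import numpy as np
import pytest

import gh57
from gh57.synthetic import (
    KNOCKOUT_MODES,
    MACHINERY_COMPLETE,
    MACHINERY_NO_DONOR,
    MACHINERY_NO_NUCLEOPHILE,
    MACHINERY_NONE,
    MIN_GROUP_DIVERGENCE,
)


class TestGroupConsensus:
    def test_catalytic_pair_in_every_enzyme_consensus(self, consensus, catalogue):
        for group in catalogue.enzyme_names:
            assert consensus[group][14] == "E"
            assert consensus[group][19] == "D"

    def test_diagnostic_residues_follow_rules(self, consensus):
        assert consensus["4AGT"][22] == "K"
        assert consensus["AAMY"][34:36] == "YY"
        assert consensus["MGA"][34:36] == "FW"
        assert consensus["AGAL"][34:36] == "GW"
        assert consensus["NSA"][34:36] == "FF"

    def test_enzyme_consensi_pairwise_divergent(self, consensus, catalogue, schema):
        free = schema.free_positions
        names = catalogue.enzyme_names
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                diffs = sum(consensus[a][p - 1] != consensus[b][p - 1] for p in free)
                assert diffs >= MIN_GROUP_DIVERGENCE

    def test_like_consensus_close_to_base_but_distinct(self, consensus, catalogue, schema):
        for like in catalogue.like_names:
            base = catalogue.base_of(like)
            diffs = sum(a != b for a, b in zip(consensus[like], consensus[base]))
            assert diffs == 10  # only free positions touched, machinery intact
            assert consensus[like][14] == "E" and consensus[like][19] == "D"

    def test_deterministic_in_seed(self):
        assert gh57.build_group_consensus(seed=11) == gh57.build_group_consensus(seed=11)
        assert gh57.build_group_consensus(seed=11) != gh57.build_group_consensus(seed=12)


class TestEmitSequence:
    def test_maltogenic_amylase_keeps_its_terminal_pair(self, consensus):
        cfg = gh57.SyntheticConfig(seed=3)
        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = gh57.emit_sequence("MGA", consensus, cfg, rng)
            assert seq.fingerprint[34:36] == "FW"

    def test_length_close_to_group_mean(self, consensus, catalogue):
        cfg = gh57.SyntheticConfig(seed=4, length_jitter=0.05)
        rng = np.random.default_rng(4)
        mean = catalogue["AAMY"].mean_length
        lengths = [len(gh57.emit_sequence("AAMY", consensus, cfg, rng).sequence) for _ in range(50)]
        sd = cfg.length_jitter * mean
        assert all(abs(ln - mean) <= 3 * sd + 1 for ln in lengths)

    def test_bacterial_only_group_gets_bacterial_taxonomy(self, consensus):
        cfg = gh57.SyntheticConfig(seed=5)
        rng = np.random.default_rng(5)
        seq = gh57.emit_sequence("GBE-like", consensus, cfg, rng)
        assert seq.taxonomy == "bacterial"

    def test_fingerprint_roundtrips_through_coordinates(self, consensus):
        cfg = gh57.SyntheticConfig(seed=6)
        rng = np.random.default_rng(6)
        for group in ("AAMY", "APU", "AGAL", "GBE-like"):
            seq = gh57.emit_sequence(group, consensus, cfg, rng)
            assert seq.extracted_fingerprint() == seq.fingerprint
            assert len(seq.fingerprint) == 36

    def test_conserved_positions_never_flip(self, consensus, schema):
        cfg = gh57.SyntheticConfig(seed=8, conservation=0.5)
        rng = np.random.default_rng(8)
        fixed = set(schema.catalytic_positions) | set(schema.diagnostic_positions)
        for _ in range(20):
            seq = gh57.emit_sequence("GBE", consensus, cfg, rng)
            for pos in fixed:
                assert seq.fingerprint[pos - 1] == consensus["GBE"][pos - 1]


class TestKnockout:
    def _seq(self, consensus, group="AAMY", seed=9):
        rng = np.random.default_rng(seed)
        return gh57.emit_sequence(group, consensus, gh57.SyntheticConfig(seed=seed), rng), rng

    def test_nucleophile_knockout_relabels_to_like_group(self, consensus):
        seq, rng = self._seq(consensus)
        out = gh57.knock_out_catalytics(seq, "nucleophile", rng)
        assert out.group == "AAMY-like"
        assert out.machinery == MACHINERY_NO_NUCLEOPHILE
        assert out.fingerprint[14] != "E"
        assert out.extracted_fingerprint() == out.fingerprint  # sequence edited too

    def test_double_knockout_status(self, consensus):
        seq, rng = self._seq(consensus, group="4AGT")
        out = gh57.knock_out_catalytics(seq, "both", rng)
        assert out.group == "4AGT-like"
        assert out.machinery == MACHINERY_NONE
        assert out.fingerprint[14] != "E" and out.fingerprint[19] != "D"

    def test_donor_knockout_leaves_nucleophile(self, consensus):
        seq, rng = self._seq(consensus, group="GBE")
        out = gh57.knock_out_catalytics(seq, "donor", rng)
        assert out.fingerprint[14] == "E"
        assert out.machinery == MACHINERY_NO_DONOR

    def test_invalid_mode_and_double_application_rejected(self, consensus):
        seq, rng = self._seq(consensus)
        with pytest.raises(ValueError):
            gh57.knock_out_catalytics(seq, "sidechain", rng)
        once = gh57.knock_out_catalytics(seq, "both", rng)
        with pytest.raises(ValueError):
            gh57.knock_out_catalytics(once, "donor", rng)

    def test_partnerless_group_rejected(self, consensus):
        seq, rng = self._seq(consensus, group="AGAL")
        with pytest.raises(ValueError):
            gh57.knock_out_catalytics(seq, "nucleophile", rng)


class TestGenerateDataset:
    def test_default_counts_match_study_catalogue(self, default_dataset, catalogue):
        non_decoys = default_dataset.non_decoys
        assert len(non_decoys) == 1602
        by_group = {}
        by_tax = {"archaeal": 0, "bacterial": 0}
        for s in non_decoys:
            by_group[s.group] = by_group.get(s.group, 0) + 1
            by_tax[s.taxonomy] += 1
        assert by_group == catalogue.counts()
        assert by_tax == {"archaeal": 383, "bacterial": 1219}
        decoys = [s for s in default_dataset.sequences if s.decoy]
        assert len(decoys) == round(0.02 * 1602)
        assert all(s.missing_csr in (1, 2, 3, 4, 5) for s in decoys)

    def test_machinery_by_construction(self, default_dataset, catalogue):
        for s in default_dataset.non_decoys:
            if catalogue[s.group].kind == "enzyme":
                assert s.machinery == MACHINERY_COMPLETE
                assert s.fingerprint[14] == "E" and s.fingerprint[19] == "D"
            else:
                assert s.machinery != MACHINERY_COMPLETE
                assert not (s.fingerprint[14] == "E" and s.fingerprint[19] == "D")

    def test_generation_is_deterministic(self):
        cfg = gh57.SyntheticConfig(seed=21, counts={"AAMY": 5, "GBE": 5, "AAMY-like": 2})
        a = gh57.generate_dataset(cfg)
        b = gh57.generate_dataset(cfg)
        assert a.to_fasta() == b.to_fasta()
        assert a.truth_table().equals(b.truth_table())

    def test_zero_counts_give_empty_dataset(self):
        cfg = gh57.SyntheticConfig(seed=1, counts={g: 0 for g in gh57.default_catalogue().names})
        ds = gh57.generate_dataset(cfg)
        assert len(ds) == 0
        assert ds.to_fasta() == ""
        assert len(ds.truth_table()) == 0

    def test_unique_ids(self, default_dataset):
        ids = [s.id for s in default_dataset.sequences]
        assert len(ids) == len(set(ids))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            gh57.SyntheticConfig(conservation=0.0)
        with pytest.raises(ValueError):
            gh57.SyntheticConfig(counts={"AAMY": -1})
        with pytest.raises(ValueError):
            gh57.SyntheticConfig(linker_composition=[1.0] * 20)
        with pytest.raises(ValueError):
            gh57.generate_dataset(gh57.SyntheticConfig(counts={"NOPE": 3}))
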