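import filecmp

import numpy as np
import pytest

from loctree.classes import DomainOfLife, class_set
from loctree.errors import ValidationError
from loctree.homology import TransferPolicy, filter_hits
from loctree.io_formats import read_blast_tab, write_blast_tab
from loctree.profile_kernel import KernelParams, feature_map
from loctree.records import SequenceRecord
from loctree.synthetic import (
    WITH_HIT,
    WITHOUT_HIT,
    ScenarioConfig,
    fabricate_hit,
    make_dataset,
    make_homolog,
    make_motifs,
    sample_sequence,
)

SMALL = dict(domain_of_life=DomainOfLife.ARCHAEA, n_per_class=4,
             n_reference_per_class=6, seq_len_range=(100, 140))


class TestMotifs:
    def test_distinct_and_reproducible(self):
        cfg = ScenarioConfig(seed=1)
        a, b = make_motifs(cfg), make_motifs(cfg)
        assert a == b
        flat = [m for motifs in a.values() for m in motifs]
        assert len(set(flat)) == len(flat)
        for i, x in enumerate(flat):
            for y in flat[i + 1:]:
                assert sum(p != q for p, q in zip(x, y)) >= 2

    def test_seed_changes_motifs(self):
        a = make_motifs(ScenarioConfig(seed=1))
        b = make_motifs(ScenarioConfig(seed=2))
        assert a != b

    def test_infeasible_space_rejected(self):
        cfg = ScenarioConfig(domain_of_life=DomainOfLife.ARCHAEA,
                             motif_len=3, motifs_per_class=300)
        with pytest.raises(ValidationError, match="too small"):
            make_motifs(cfg)


class TestSampleSequence:
    def test_motifs_planted_as_substrings(self):
        cfg = ScenarioConfig(**SMALL)
        motifs = make_motifs(cfg)
        rng = np.random.default_rng(3)
        rec = sample_sequence("cytosol", motifs, cfg, rng)
        assert any(m in rec.residues for m in motifs["cytosol"])

    def test_zero_probability_letter_absent_outside_motifs(self):
        bg = [0.0] + [1.0 / 19] * 19  # letter 'A' never drawn as background
        cfg = ScenarioConfig(**SMALL, background=tuple(bg))
        motifs = {"cytosol": ["CCCCCCCC"]}
        rng = np.random.default_rng(4)
        rec = sample_sequence("cytosol", motifs, cfg, rng)
        assert "A" not in rec.residues

    def test_deterministic_for_fixed_state(self):
        cfg = ScenarioConfig(**SMALL)
        motifs = make_motifs(cfg)
        a = sample_sequence("cytosol", motifs, cfg, np.random.default_rng(9))
        b = sample_sequence("cytosol", motifs, cfg, np.random.default_rng(9))
        assert a.residues == b.residues


class TestMakeHomolog:
    def test_target_100_is_identity(self):
        seq = SequenceRecord("s", "MKVACDEFGH" * 10)
        hom, realized = make_homolog(seq, 100.0, np.random.default_rng(1))
        assert hom.residues == seq.residues and realized == 100.0

    def test_exact_substitution_count(self):
        seq = SequenceRecord("s", "MKVACDEFGH" * 10)  # L = 100
        hom, realized = make_homolog(seq, 60.0, np.random.default_rng(2))
        n_diff = sum(a != b for a, b in zip(seq.residues, hom.residues))
        assert n_diff == 40 and realized == 60.0

    def test_realized_matches_direct_identity_count(self):
        rng = np.random.default_rng(5)
        for target in (30.0, 55.5, 80.0):
            seq = SequenceRecord("s", "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=173)))
            hom, realized = make_homolog(seq, target, rng)
            direct = 100.0 * sum(a == b for a, b in
                                 zip(seq.residues, hom.residues)) / len(seq)
            assert realized == pytest.approx(direct)
            assert abs(realized - target) <= 1.0  # within a point for L >= 100

    def test_zero_target_rejected(self):
        with pytest.raises(ValidationError):
            make_homolog(SequenceRecord("s", "MKV"), 0.0,
                         np.random.default_rng(0))


class TestFabricatedHits:
    def test_evalue_proxy(self):
        q = SequenceRecord("q", "M" * 100)
        r = SequenceRecord("r", "M" * 100)
        assert fabricate_hit(q, r, 60.0).evalue == pytest.approx(1e-12)
        assert fabricate_hit(q, r, 0.0).evalue == pytest.approx(1.0)

    def test_round_trip_through_tabular(self, tmp_path):
        q = SequenceRecord("q", "M" * 120)
        r = SequenceRecord("r", "M" * 110)
        hit = fabricate_hit(q, r, 61.905)
        path = tmp_path / "hits.tsv"
        write_blast_tab([hit], path)
        (back,) = read_blast_tab(path)
        assert back.pide == hit.pide
        assert back.evalue == pytest.approx(hit.evalue)


class TestMakeDataset:
    def test_split_counts_forced_by_fraction(self):
        ds = make_dataset(ScenarioConfig(homolog_fraction=0.5, seed=0))
        assert len(ds.query_ids(WITH_HIT)) == 60
        assert len(ds.query_ids(WITHOUT_HIT)) == 60
        assert len(ds.records) == 120

    def test_zero_fraction_means_no_hits(self):
        ds = make_dataset(ScenarioConfig(**SMALL, homolog_fraction=0.0, seed=1))
        assert ds.hits == []
        assert set(ds.split.values()) == {WITHOUT_HIT}

    def test_truth_covers_all_records(self):
        ds = make_dataset(ScenarioConfig(**SMALL, seed=2))
        assert all(r.id in ds.truth for r in ds.records)
        assert all(r.id in ds.reference_truth for r in ds.reference_records)

    def test_with_hit_queries_hit_reference_subjects(self):
        ds = make_dataset(ScenarioConfig(**SMALL, seed=3))
        ref_ids = set(ds.reference_db_ids)
        grouped = ds.hits_by_query()
        for qid in ds.query_ids(WITH_HIT):
            assert grouped[qid] and all(h.subject_id in ref_ids
                                        for h in grouped[qid])
        for qid in ds.query_ids(WITHOUT_HIT):
            assert grouped[qid] == []

    def test_split_recoverable_from_hits_and_default_policy(self):
        for decoys in (False, True):
            ds = make_dataset(ScenarioConfig(**SMALL, seed=4,
                                             decoy_hits=decoys))
            grouped = ds.hits_by_query()
            policy = TransferPolicy()
            for qid, split in ds.split.items():
                surviving = filter_hits(grouped[qid], qid, policy,
                                        ds.reference_truth)
                assert bool(surviving) == (split == WITH_HIT)

    def test_decoy_hits_fail_default_gate_but_exist(self):
        ds = make_dataset(ScenarioConfig(**SMALL, seed=5, decoy_hits=True))
        grouped = ds.hits_by_query()
        for qid in ds.query_ids(WITHOUT_HIT):
            assert grouped[qid]
            assert all(h.evalue > 1e-3 for h in grouped[qid])

    def test_byte_identical_files_for_fixed_seed(self, tmp_path):
        cfg = ScenarioConfig(**SMALL, seed=6)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_dataset(cfg).write(d1)
        make_dataset(cfg).write(d2)
        for name in ("queries.fasta", "reference.fasta", "truth.tsv",
                     "reference_annotations.tsv", "hits.tsv", "scenario.json"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_nearest_centroid_baseline_and_tree_beat_chance(
            self, archaea_dataset, archaea_model):
        """Separability guard: a nearest-centroid baseline over k-mer counts
        beats chance, and the trained tree does at least as well."""
        from loctree.hierarchical import predict_de_novo
        from loctree.evaluation import qn
        ds = archaea_dataset
        params = KernelParams(k=3)
        classes = class_set(DomainOfLife.ARCHAEA)
        centroids = {}
        for cls in classes:
            members = [p for p in ds.reference_profiles
                       if ds.reference_truth[p.id] == cls]
            acc: dict[int, float] = {}
            for prof in members:
                fv = feature_map(prof, params)
                for code, cnt in zip(fv.codes, fv.count_values):
                    acc[int(code)] = acc.get(int(code), 0.0) + float(cnt)
            norm = np.sqrt(sum(v * v for v in acc.values()))
            centroids[cls] = {c: v / norm for c, v in acc.items()}
        fresh = set(ds.query_ids(WITHOUT_HIT))
        eval_profiles = [p for p in ds.profiles if p.id in fresh]
        correct = 0
        for prof in eval_profiles:
            fv = feature_map(prof, params)
            best_cls, best_sim = None, -1.0
            for cls, cen in centroids.items():
                sim = sum(cen.get(int(c), 0.0) * float(v)
                          for c, v in zip(fv.codes, fv.count_values)) / fv.norm
                if sim > best_sim:
                    best_cls, best_sim = cls, sim
            correct += best_cls == ds.truth[prof.id]
        baseline = 100.0 * correct / len(eval_profiles)
        chance = 100.0 / len(classes)
        assert baseline > chance
        preds = [predict_de_novo(p, archaea_model) for p in eval_profiles]
        assert qn(preds, ds.truth) >= baseline
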