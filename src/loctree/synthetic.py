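"""Synthetic dataset generator.

Emulates the statistical structure the predictor assumes, with no claim of
biological realism: each localization class is marked by a few short planted
motifs (so classes are separable by k-mer content), a reference set plays
the annotated database, and a controlled fraction of the queries are mutated
copies of reference proteins at a target percentage identity, with
fabricated tabular hit records — so the homology route, the de novo route
and the combiner are all exercised without any external search tool.

The fabricated E-value is an explicit monotone proxy of identity,
``evalue = 10 ** (-0.2 * pide)``, not a claim about alignment statistics: a
60%-identity homolog gets 1e-12 (passes the 1e-3 gate), while decoy hits at
PIDE < 15 get E-values above 1e-3 and fail it.

Substitutions in homologs fall uniformly, with no protection of planted
motifs; highly diverged homologs therefore genuinely degrade the de novo
signal as well.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from loctree.classes import DomainOfLife, class_set, default_k
from loctree.errors import ValidationError
from loctree.io_formats import (
    fabricate_profile,
    write_annotations,
    write_blast_tab,
    write_fasta,
)
from loctree.records import (
    ALPHABET,
    AnnotationDB,
    BlastHit,
    SequenceProfile,
    SequenceRecord,
)

__all__ = [
    "ScenarioConfig",
    "SyntheticDataset",
    "fabricate_hit",
    "make_dataset",
    "make_homolog",
    "make_motifs",
    "sample_sequence",
]

WITH_HIT = "WITH_HIT"
WITHOUT_HIT = "WITHOUT_HIT"

# decoy hits for WITHOUT_HIT queries: PIDE below this keeps the E-value proxy
# above the 1e-3 gate (10**(-0.2*15) = 10**-3)
_DECOY_PIDE_RANGE = (2.0, 12.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions of one synthetic benchmark.

    Defaults describe the standard scenario: the 6 bacterial classes with 50
    reference (training/database) proteins and 20 queries per class,
    sequences of 150-250 residues, 2 motifs of length 8 per class planted 3
    times each, uniform background, half the queries being 60%-identity
    homologs of reference proteins.
    """

    domain_of_life: DomainOfLife = DomainOfLife.BACTERIA
    n_per_class: int = 20
    n_reference_per_class: int = 50
    seq_len_range: tuple[int, int] = (150, 250)
    motifs_per_class: int = 2
    motif_len: int = 8
    motif_insertions_per_seq: int = 3
    background: tuple[float, ...] = tuple([1.0 / 20] * 20)
    homolog_fraction: float = 0.5
    target_pide: float = 60.0
    decoy_hits: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif_len < default_k(self.domain_of_life):
            raise ValidationError(
                f"motif_len {self.motif_len} shorter than the domain's "
                f"kernel k = {default_k(self.domain_of_life)}")
        if not 0.0 <= self.homolog_fraction <= 1.0:
            raise ValidationError("homolog_fraction outside [0,1]")
        if min(self.n_per_class, self.n_reference_per_class,
               self.motifs_per_class, self.motif_insertions_per_seq) < 1:
            raise ValidationError("all counts must be >= 1")
        if len(self.background) != len(ALPHABET):
            raise ValidationError("background must have 20 frequencies")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ValidationError("background frequencies must be a distribution")
        lo, hi = self.seq_len_range
        if lo > hi or lo < self.motif_insertions_per_seq * self.motif_len:
            raise ValidationError(
                "seq_len_range too small for the requested motif insertions")


@dataclass
class SyntheticDataset:
    """Queries, their profiles and truth, the reference database, and the
    fabricated hits connecting the two."""

    config: ScenarioConfig
    records: list[SequenceRecord]
    profiles: list[SequenceProfile]
    truth: AnnotationDB
    hits: list[BlastHit]
    split: dict[str, str]
    reference_records: list[SequenceRecord]
    reference_profiles: list[SequenceProfile]
    reference_truth: AnnotationDB
    motifs: dict[str, list[str]] = field(default_factory=dict)

    @property
    def reference_db_ids(self) -> list[str]:
        return [r.id for r in self.reference_records]

    def hits_by_query(self) -> dict[str, list[BlastHit]]:
        grouped: dict[str, list[BlastHit]] = {r.id: [] for r in self.records}
        for h in self.hits:
            grouped.setdefault(h.query_id, []).append(h)
        return grouped

    def query_ids(self, split: str | None = None) -> list[str]:
        if split is None:
            return [r.id for r in self.records]
        return [r.id for r in self.records if self.split[r.id] == split]

    def write(self, out_dir: str | os.PathLike) -> None:
        """Write queries.fasta, reference.fasta, truth.tsv,
        reference_annotations.tsv, hits.tsv and scenario.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, out / "queries.fasta")
        write_fasta(self.reference_records, out / "reference.fasta")
        write_annotations(self.truth, out / "truth.tsv")
        write_annotations(self.reference_truth, out / "reference_annotations.tsv")
        write_blast_tab(self.hits, out / "hits.tsv")
        payload = asdict(self.config)
        payload["domain_of_life"] = self.config.domain_of_life.value
        payload["split"] = dict(sorted(self.split.items()))
        (out / "scenario.json").write_text(
            json.dumps(payload, sort_keys=True, indent=1) + "\n")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def make_motifs(config: ScenarioConfig,
                rng: np.random.Generator | None = None
                ) -> dict[str, list[str]]:
    """Seeded, mutually distinct motifs (pairwise Hamming >= 2) per class."""
    classes = class_set(config.domain_of_life)
    total = len(classes) * config.motifs_per_class
    if 20 ** config.motif_len < total * 10:
        raise ValidationError(
            f"motif space 20**{config.motif_len} too small for {total} motifs")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    letters = np.array(list(ALPHABET))
    accepted: list[str] = []
    attempts = 0
    while len(accepted) < total:
        attempts += 1
        if attempts > 1000 * total:
            raise ValidationError("could not draw mutually distinct motifs")
        cand = "".join(rng.choice(letters, size=config.motif_len))
        if all(_hamming(cand, m) >= 2 for m in accepted):
            accepted.append(cand)
    return {
        cls: accepted[i * config.motifs_per_class:(i + 1) * config.motifs_per_class]
        for i, cls in enumerate(classes)
    }


def sample_sequence(cls: str, motifs: dict[str, list[str]],
                    config: ScenarioConfig, rng: np.random.Generator,
                    id: str = "synthetic") -> SequenceRecord:
    """Background-sampled sequence with class motifs planted non-overlapping.

    Insertion starts are drawn uniformly over all non-overlapping placements
    via the standard gap bijection (choose sorted distinct offsets, then
    shift each by its index times motif_len - 1).
    """
    if cls not in motifs:
        raise ValidationError(f"no motifs for class {cls!r}")
    lo, hi = config.seq_len_range
    length = int(rng.integers(lo, hi + 1))
    m, ins = config.motif_len, config.motif_insertions_per_seq
    if length < ins * m:
        raise ValidationError(f"length {length} cannot host {ins} x {m} motifs")
    letters = np.array(list(ALPHABET))
    seq = rng.choice(letters, size=length, p=np.array(config.background))
    n_offsets = length - m - (ins - 1) * (m - 1) + 1
    offsets = np.sort(rng.choice(n_offsets, size=ins, replace=False))
    for i, off in enumerate(offsets):
        start = int(off) + i * (m - 1)
        motif = motifs[cls][int(rng.integers(len(motifs[cls])))]
        seq[start:start + m] = list(motif)
    return SequenceRecord(id, "".join(seq))


def make_homolog(seq: SequenceRecord, target_pide: float,
                 rng: np.random.Generator,
                 id: str | None = None) -> tuple[SequenceRecord, float]:
    """Mutated copy at approximately *target_pide* percent identity.

    Exactly ``round((1 - pide/100) * L)`` positions (drawn without
    replacement) are substituted with a different letter; the realized
    identity ``100 * unchanged / L`` is returned alongside.
    """
    if not 0.0 < target_pide <= 100.0:
        raise ValidationError(f"target_pide {target_pide} outside (0,100]")
    length = len(seq)
    n_sub = int(round((1.0 - target_pide / 100.0) * length))
    residues = list(seq.residues)
    if n_sub > 0:
        positions = rng.choice(length, size=n_sub, replace=False)
        for pos in positions:
            original = residues[pos]
            alternatives = [a for a in ALPHABET if a != original]
            residues[pos] = alternatives[int(rng.integers(len(alternatives)))]
    realized = 100.0 * (length - n_sub) / length
    return SequenceRecord(id or f"{seq.id}_hom", "".join(residues)), realized


def fabricate_hit(query: SequenceRecord, reference: SequenceRecord,
                  realized_pide: float) -> BlastHit:
    """Full-length hit record with the documented E-value proxy."""
    if not 0.0 <= realized_pide <= 100.0:
        raise ValidationError(f"realized_pide {realized_pide} outside [0,100]")
    aln = len(query)
    pide = round(realized_pide, 3)
    return BlastHit(
        query_id=query.id,
        subject_id=reference.id,
        pide=pide,
        aln_length=aln,
        mismatches=int(round((1.0 - pide / 100.0) * aln)),
        gapopens=0,
        qstart=1, qend=len(query),
        sstart=1, send=len(reference),
        evalue=10.0 ** (-0.2 * pide),
        bitscore=round(2.0 * aln * pide / 100.0, 1),
    )


def make_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Reference database + query set with a controlled homolog fraction.

    Per class: ``n_reference_per_class`` reference proteins (annotated, used
    for training and as transfer subjects) and ``n_per_class`` queries, of
    which ``round(homolog_fraction * n_per_class)`` are mutated copies of
    distinct reference proteins (WITH_HIT, one fabricated hit each) and the
    rest fresh draws (WITHOUT_HIT; decoy hits only if configured).
    """
    rng = np.random.default_rng(config.seed)
    motifs = make_motifs(config, rng)
    classes = class_set(config.domain_of_life)

    reference_records: list[SequenceRecord] = []
    reference_entries: dict[str, str] = {}
    refs_by_class: dict[str, list[SequenceRecord]] = {}
    for ci, cls in enumerate(classes):
        refs_by_class[cls] = []
        for i in range(config.n_reference_per_class):
            rec = sample_sequence(cls, motifs, config, rng,
                                  id=f"REF{ci:02d}_{i:04d}")
            reference_records.append(rec)
            reference_entries[rec.id] = cls
            refs_by_class[cls].append(rec)

    n_with = int(round(config.homolog_fraction * config.n_per_class))
    records: list[SequenceRecord] = []
    truth_entries: dict[str, str] = {}
    hits: list[BlastHit] = []
    split: dict[str, str] = {}
    for ci, cls in enumerate(classes):
        # homolog queries copy distinct reference proteins of the class
        n_pool = len(refs_by_class[cls])
        chosen = rng.choice(n_pool, size=min(n_with, n_pool), replace=False)
        for j, ref_idx in enumerate(chosen):
            source = refs_by_class[cls][int(ref_idx)]
            query, realized = make_homolog(
                source, config.target_pide, rng, id=f"QRY{ci:02d}_{j:04d}H")
            records.append(query)
            truth_entries[query.id] = cls
            split[query.id] = WITH_HIT
            hits.append(fabricate_hit(query, source, realized))
        for j in range(config.n_per_class - len(chosen)):
            query = sample_sequence(cls, motifs, config, rng,
                                    id=f"QRY{ci:02d}_{j:04d}D")
            records.append(query)
            truth_entries[query.id] = cls
            split[query.id] = WITHOUT_HIT
            if config.decoy_hits:
                decoy_ref = reference_records[int(rng.integers(len(reference_records)))]
                decoy_pide = float(rng.uniform(*_DECOY_PIDE_RANGE))
                hits.append(fabricate_hit(query, decoy_ref, decoy_pide))

    return SyntheticDataset(
        config=config,
        records=records,
        profiles=[fabricate_profile(r) for r in records],
        truth=AnnotationDB(truth_entries, config.domain_of_life),
        hits=hits,
        split=split,
        reference_records=reference_records,
        reference_profiles=[fabricate_profile(r) for r in reference_records],
        reference_truth=AnnotationDB(reference_entries, config.domain_of_life),
        motifs=motifs,
    )
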