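"""Readers and writers for every external format the package touches.

FASTA goes through Biopython.  The PSSM reader understands the NCBI ASCII
dialect (``psiblast -out_ascii_pssm``): header lines, then one row per
position carrying the position index, the query residue, 20 integer log-odds
columns and 20 percentage columns.  Only the percentage columns are used;
they are the estimated per-position residue probabilities the kernel needs,
converted to the internal -ln(p) scale with p clamped to [0.001, 1].

Hit lists are the 12-column tabular format (``-outfmt 6``): qseqid sseqid
pident length mismatch gapopen qstart qend sstart send evalue bitscore.
"""

from __future__ import annotations

import csv
import math
import os
import re
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from loctree.classes import DomainOfLife
from loctree.errors import FormatError, ValidationError
from loctree.records import (
    ALPHABET,
    ALPHABET_INDEX,
    PROB_FLOOR,
    AnnotationDB,
    BlastHit,
    Prediction,
    PredictionSource,
    ProfileSource,
    SequenceProfile,
    SequenceRecord,
)

__all__ = [
    "fabricate_profile",
    "read_annotations",
    "read_blast_tab",
    "read_fasta",
    "read_predictions",
    "read_pssm",
    "write_annotations",
    "write_blast_tab",
    "write_fasta",
    "write_predictions",
]

# rare/ambiguous letters folded into X so that no position is dropped
_NONSTANDARD = str.maketrans({c: "X" for c in "BZUOJ"})

PREDICTION_COLUMNS = (
    "protein_id",
    "reliability_index",
    "expected_accuracy",
    "localization_class",
    "go_terms",
    "source",
)

# external labels of the two prediction routes, as printed in column 6
SOURCE_LABELS = {
    PredictionSource.HOMOLOGY: "PSI-BLAST",
    PredictionSource.DE_NOVO: "LocTree2",
}
_SOURCE_FROM_LABEL = {v: k for k, v in SOURCE_LABELS.items()}


def _canonicalize(raw: str, rec_id: str) -> str:
    seq = raw.strip().upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    seq = seq.translate(_NONSTANDARD)
    if not seq:
        raise FormatError(f"{rec_id}: zero-length sequence")
    return seq


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Lowercase letters are uppercased, B/Z/U/O/J map to X, a terminal '*'
    is stripped.  Duplicate ids and residues outside the 21-letter alphabet
    are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for bio in parsed:
        if bio.id in seen:
            raise FormatError(f"duplicate sequence id {bio.id!r} in {path}")
        seen.add(bio.id)
        desc = bio.description[len(bio.id):].strip() if bio.description else ""
        residues = _canonicalize(str(bio.seq), bio.id)
        try:
            records.append(SequenceRecord(bio.id, residues, desc))
        except ValidationError as exc:
            raise FormatError(str(exc)) from exc
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | os.PathLike) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def fabricate_profile(record: SequenceRecord, p_self: float = 0.9) -> SequenceProfile:
    """Deterministic pseudo-profile from the sequence alone.

    The observed residue gets probability mass ``p_self``; the remaining mass
    is spread uniformly over the other 19 letters.  X positions get a uniform
    column.  Used as the de novo fallback when no real PSSM is supplied.
    """
    if not 0.0 < p_self < 1.0:
        raise ValidationError(f"p_self {p_self} outside (0,1)")
    n = len(ALPHABET)
    s_other = -math.log(max((1.0 - p_self) / (n - 1), PROB_FLOOR))
    s_self = -math.log(p_self)
    s_uniform = -math.log(1.0 / n)
    scores = np.full((len(record), n), s_other, dtype=float)
    for i, aa in enumerate(record.residues):
        if aa == "X":
            scores[i, :] = s_uniform
        else:
            scores[i, ALPHABET_INDEX[aa]] = s_self
    return SequenceProfile(record.id, scores, ProfileSource.FABRICATED,
                           residues=record.residues)


_PSSM_ROW = re.compile(r"^\s*(\d+)\s+([A-Za-z*])\s+(.*)$")


def read_pssm(path: str | os.PathLike, id: str | None = None) -> SequenceProfile:
    """Parse an NCBI ASCII PSSM into a profile on the internal score scale.

    Rows must carry 40 numeric columns (20 log-odds then 20 percentages);
    trailing per-row statistics (information content, relative weight) are
    tolerated and ignored.  The profile id defaults to the file stem.
    """
    path = Path(path)
    header_order: list[str] | None = None
    rows: list[np.ndarray] = []
    residues: list[str] = []
    expected_index = 1
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        tokens = stripped.split()
        if header_order is None and len(tokens) >= 40 and all(
            len(t) == 1 and t.isalpha() for t in tokens[:40]
        ):
            header_order = tokens[:40]
            continue
        m = _PSSM_ROW.match(line)
        if not m:
            continue
        idx = int(m.group(1))
        fields = m.group(3).split()
        if len(fields) < 40:
            raise FormatError(f"{path}: truncated PSSM row {idx}")
        if idx != expected_index:
            raise FormatError(f"{path}: PSSM rows out of order at {idx}")
        expected_index += 1
        try:
            percentages = np.array([float(x) for x in fields[20:40]])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric field in row {idx}") from exc
        rows.append(percentages)
        residues.append(m.group(2).upper())
    if not rows:
        raise FormatError(f"{path}: no PSSM rows found")
    if header_order is None:
        header_order = list(ALPHABET) * 2
    pct = np.vstack(rows)
    # reorder percentage columns into the internal alphabet order
    col_letters = header_order[20:40]
    order = np.empty(len(ALPHABET), dtype=int)
    for j, letter in enumerate(col_letters):
        if letter not in ALPHABET_INDEX:
            raise FormatError(f"{path}: unexpected PSSM column letter {letter!r}")
        order[ALPHABET_INDEX[letter]] = j
    probs = np.clip(pct[:, order] / 100.0, PROB_FLOOR, 1.0)
    scores = -np.log(probs)
    try:
        return SequenceProfile(
            id or path.stem, scores, ProfileSource.PARSED_PSSM,
            residues="".join(r if r in ALPHABET_INDEX else "X" for r in residues),
        )
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_blast_tab(path: str | os.PathLike) -> list[BlastHit]:
    """Read 12-column tabular hits; hits are returned in file order."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pide=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gapopens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_blast_tab(hits: list[BlastHit], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pide:.3f}\t{h.aln_length}\t"
                f"{h.mismatches}\t{h.gapopens}\t{h.qstart}\t{h.qend}\t"
                f"{h.sstart}\t{h.send}\t{h.evalue:g}\t{h.bitscore:g}\n"
            )


def read_annotations(path: str | os.PathLike,
                     domain_of_life: DomainOfLife) -> AnnotationDB:
    """Read an id<TAB>class table, validating labels against the domain."""
    entries: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            pid, cls = fields
            if pid in entries and entries[pid] != cls:
                raise FormatError(
                    f"{path}:{lineno}: {pid} annotated with conflicting "
                    f"classes {entries[pid]!r} and {cls!r}"
                )
            entries[pid] = cls
    return AnnotationDB(entries, domain_of_life)


def write_annotations(db: AnnotationDB, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for pid, cls in db.entries.items():
            fh.write(f"{pid}\t{cls}\n")


def _format_go(go_terms: list[tuple[str, str]]) -> str:
    return ",".join(f"{name} {goid}" for name, goid in go_terms)


def _parse_go(cell: str) -> list[tuple[str, str]]:
    terms = []
    for token in cell.split(","):
        token = token.strip()
        if not token:
            continue
        name, _, goid = token.rpartition(" ")
        terms.append((name, goid))
    return terms


def write_predictions(predictions: list[Prediction],
                      path: str | os.PathLike) -> None:
    """Write the six-column per-protein output table.

    Columns: protein id, reliability index, expected accuracy, localization
    class, GO terms ("name GO:NNNNNNN", comma-joined) and the source route
    (PSI-BLAST for homology transfer, LocTree2 for de novo).
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PREDICTION_COLUMNS)
        for p in predictions:
            ea = "n/a" if p.expected_accuracy is None else f"{p.expected_accuracy:g}"
            writer.writerow([
                p.id, p.ri, ea, p.loc_class, _format_go(p.go_terms),
                SOURCE_LABELS[p.source],
            ])


def read_predictions(path: str | os.PathLike) -> list[Prediction]:
    """Read a prediction table back (decision paths/hits are not persisted)."""
    preds: list[Prediction] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != list(PREDICTION_COLUMNS):
            raise FormatError(f"{path}: unexpected prediction header {header!r}")
        for fields in reader:
            if len(fields) != 6:
                raise FormatError(f"{path}: expected 6 columns, got {len(fields)}")
            pid, ri, ea, cls, go, source_label = fields
            if source_label not in _SOURCE_FROM_LABEL:
                raise FormatError(f"{path}: unknown source {source_label!r}")
            source = _SOURCE_FROM_LABEL[source_label]
            # reconstruct a minimally valid record for evaluation purposes
            placeholder_path = [("?", "pos", 1.0)] if source is PredictionSource.DE_NOVO else []
            placeholder_hit = (
                BlastHit(pid, "?", 0.0, 0, 0, 0, 1, 1, 1, 1, 0.0, 0.0)
                if source is PredictionSource.HOMOLOGY else None
            )
            preds.append(Prediction(
                id=pid,
                loc_class=cls,
                ri=int(ri),
                source=source,
                expected_accuracy=None if ea == "n/a" else float(ea),
                go_terms=_parse_go(go),
                path=placeholder_path,
                hit=placeholder_hit,
            ))
    return preds
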