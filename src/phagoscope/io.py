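"""File formats: FASTA, FASTQ, TSV tables, BLAST tabular hits, SAM.

Interchange conventions: 0-based half-open coordinates everywhere; TSV
tables carry ``#``-prefixed header comments (tool version, seed, config
hash) that readers skip; FASTQ is 4-line Sanger-encoded.
"""

from __future__ import annotations

import hashlib
import json
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignmentHit
from .seqs import decode, encode
from .simulate import ReadSet

__all__ = [
    "read_fasta", "write_fasta", "read_fastq", "write_fastq",
    "read_table", "write_table", "read_blast_outfmt6", "read_sam_hits",
    "sha256_file", "config_hash",
]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, np.ndarray]:
    """Free-wrap FASTA to a dict of encoded sequences."""
    return {rec.id: encode(str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: Mapping[str, np.ndarray], width: int = 70) -> None:
    records = [SeqRecord(Seq(decode(np.asarray(s, np.uint8))), id=sid,
                         description="") for sid, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# FASTQ (4-line Sanger); the hand-rolled reader reports the offending line
# number on malformed records, which the error contract requires.


def write_fastq(path, reads: ReadSet) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(reads.ids, reads.seqs):
            seq = decode(row)
            fh.write(f"@{rid}\n{seq}\n+\n{reads.quality_char * len(seq)}\n")


def read_fastq(path) -> tuple[list[str], list[np.ndarray]]:
    """Parse 4-line FASTQ; raises ValueError naming the line number on
    truncated records or sequence/quality length mismatch."""
    ids: list[str] = []
    seqs: list[np.ndarray] = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            if not header.startswith("@"):
                raise ValueError(f"line {lineno}: FASTQ header must start with @")
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ValueError(f"line {lineno}: truncated FASTQ record")
            lineno += 3
            seq = seq.strip()
            qual = qual.strip()
            if not plus.startswith("+"):
                raise ValueError(f"line {lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise ValueError(
                    f"line {lineno}: quality length {len(qual)} does not "
                    f"match sequence length {len(seq)}")
            ids.append(header[1:].strip().split()[0])
            seqs.append(encode(seq))
    return ids, seqs


def read_fastq_as_readset(path) -> ReadSet:
    ids, seqs = read_fastq(path)
    if not ids:
        return ReadSet(ids=[], seqs=np.empty((0, 0), np.uint8))
    lengths = {len(s) for s in seqs}
    if len(lengths) == 1:
        mat = np.vstack(seqs)
    else:  # pad is not meaningful; keep a ragged object wrapper
        raise ValueError("reads of mixed length are not supported as a batch; "
                         "split the FASTQ by read length")
    return ReadSet(ids=ids, seqs=mat)


# ---------------------------------------------------------------------------
# TSV tables with comment headers


def write_table(path, df: pd.DataFrame, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")


def read_table(path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_metadata(path, meta: pd.DataFrame, header_lines=()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        meta.to_csv(fh, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#")
    if not {"sample_id", "group"} <= set(meta.columns):
        raise ValueError("metadata needs sample_id and group columns")
    return meta


# ---------------------------------------------------------------------------
# External alignment adapters


_OUTFMT6_COLS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                 "gapopen", "qstart", "qend", "sstart", "send", "evalue",
                 "bitscore"]


def read_blast_outfmt6(path) -> list[AlignmentHit]:
    """Parse BLAST tabular (outfmt 6) rows into alignment hits.

    BLAST reports 1-based inclusive coordinates; they are converted to
    0-based half-open, and a subject start greater than its end marks the
    minus strand.
    """
    df = pd.read_csv(path, sep="\t", names=_OUTFMT6_COLS, comment="#")
    hits = []
    for r in df.itertuples():
        sstart, send = int(r.sstart), int(r.send)
        strand = "+" if send >= sstart else "-"
        lo, hi = (sstart, send) if strand == "+" else (send, sstart)
        hits.append(AlignmentHit(
            query_id=str(r.qseqid), subject_id=str(r.sseqid),
            percent_identity=float(r.pident), aligned_length=int(r.length),
            score=float(r.bitscore), e_value=float(r.evalue),
            query_span=(int(r.qstart) - 1, int(r.qend)),
            subject_span=(lo - 1, hi), strand=strand))
    return hits


def read_sam_hits(path) -> list[AlignmentHit]:
    """Read mapped records of a (text) SAM file as alignment hits.

    Identity is derived from the NM tag when present; the SAM score field
    is the AS tag when present, else the mapped length.
    """
    import pysam

    hits = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            alen = rec.query_alignment_length
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            ident = 100.0 * max(alen - nm, 0) / alen if alen else 0.0
            score = float(rec.get_tag("AS")) if rec.has_tag("AS") else float(alen)
            hits.append(AlignmentHit(
                query_id=rec.query_name, subject_id=rec.reference_name,
                percent_identity=ident, aligned_length=alen, score=score,
                e_value=np.nan,
                query_span=(rec.query_alignment_start, rec.query_alignment_end),
                subject_span=(rec.reference_start, rec.reference_end),
                strand="-" if rec.is_reverse else "+"))
    return hits


# ---------------------------------------------------------------------------
# Checksums


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(obj) -> str:
    """Stable hash of a JSON-serialisable configuration mapping."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]
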