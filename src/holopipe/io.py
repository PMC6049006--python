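"""Readers and writers for the pipeline's on-disk dialects.

FASTA/FASTQ go through Biopython's SeqIO with transparent gzip by file
extension; the k-mer histogram and depth tables are plain
whitespace-separated text in the common ``.histo`` layout.
All writers round-trip: reading back yields equal in-memory objects.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError
from .spectrum import KmerHistogram


def _open(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA(.gz) into (id, sequence) pairs; case preserved."""
    try:
        with _open(path, "r") as fh:
            return [(r.id, str(r.seq)) for r in SeqIO.parse(fh, "fasta")]
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    with _open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read FASTQ(.gz) into (id, sequence, quality) triples."""
    try:
        with _open(path, "r") as fh:
            out = []
            for r in SeqIO.parse(fh, "fastq"):
                qual = "".join(chr(q + 33) for q in r.letter_annotations["phred_quality"])
                out.append((r.id, str(r.seq), qual))
            return out
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    with _open(path, "w") as fh:
        for rid, seq, qual in records:
            if len(qual) != len(seq):
                raise ParseError(
                    f"read {rid!r}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# histogram / depth tables


def read_histogram(path, k: int = 21) -> KmerHistogram:
    """Two whitespace-separated integer columns: depth, #distinct k-mers."""
    h: dict[int, int] = {}
    with _open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                depth, count = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            h[depth] = h.get(depth, 0) + count
    return KmerHistogram(k=k, h=h)


def write_histogram(hist: KmerHistogram, path) -> None:
    with _open(path, "w") as fh:
        for depth in sorted(hist.h):
            fh.write(f"{depth}\t{hist.h[depth]}\n")


def read_depth_table(path) -> dict[str, list[float]]:
    """``contig_id<TAB>depth[<TAB>depth2...]`` rows."""
    out: dict[str, list[float]] = {}
    with _open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns")
            try:
                out[parts[0]] = [float(x) for x in parts[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric depth") from exc
    return out


def write_depth_table(depths: dict[str, Sequence[float] | float], path) -> None:
    with _open(path, "w") as fh:
        for cid in depths:
            v = depths[cid]
            vals = v if isinstance(v, (list, tuple)) else [v]
            fh.write(cid + "\t" + "\t".join(f"{x:g}" for x in vals) + "\n")


def read_truth_table(path) -> dict[str, str]:
    """``id<TAB>genome_id`` sidecar truth tables."""
    out = {}
    with _open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns")
            out[parts[0]] = parts[1]
    return out


def write_truth_table(truth: dict[str, str], path, extra: dict[str, float] | None = None) -> None:
    with _open(path, "w") as fh:
        for key in truth:
            if extra is not None and key in extra:
                fh.write(f"{key}\t{truth[key]}\t{extra[key]:g}\n")
            else:
                fh.write(f"{key}\t{truth[key]}\n")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def contig_header(contig_id: str, genome_id: str | None) -> str:
    """FASTA header carrying a truth label, ``id|genome=<genome_id>``."""
    if genome_id is None:
        return contig_id
    return f"{contig_id}|genome={genome_id}"


def parse_contig_header(header: str) -> tuple[str, str | None]:
    if "|genome=" in header:
        cid, gid = header.split("|genome=", 1)
        return cid, gid
    return header, None
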