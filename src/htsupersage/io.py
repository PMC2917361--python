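"""Readers and writers for the pipeline's interchange formats.

FASTA/FASTQ parsing is delegated to Biopython; tabular artifacts use a plain
TSV dialect (tab-separated, no quoting, '#' comment lines) matching the
public tag-count submission format (tag, count per line).  All writers are
deterministic; all readers reject malformed input rather than repairing it.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .demux import ExtractionStats
from .enzymes import AnchoringEnzyme, Transcript, VirtualTagIndex, get_enzyme
from .profiles import TagCountProfile
from .simulate import SimulationTruth, ReadProvenance

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_profile",
    "write_profile",
    "write_stats",
    "write_virtual_tag_index",
    "write_truth",
    "read_truth",
]


def _open_text(path: "str | Path", mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: "str | Path") -> list[Transcript]:
    """Load a transcript set from FASTA.

    gene_id is the first whitespace-delimited header token; sequences are
    uppercased and U is converted to T (RNA input).  Empty files and
    duplicate ids are errors.
    """
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            parts = header.split(None, 1)
            gene_id = parts[0]
            description = parts[1] if len(parts) > 1 else ""
            if gene_id in seen:
                raise ValueError(f"{path}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            transcripts.append(
                Transcript(
                    gene_id=gene_id,
                    sequence=seq.upper().replace("U", "T"),
                    description=description,
                )
            )
    if not transcripts:
        raise ValueError(f"{path}: no FASTA records")
    return transcripts


def write_fasta(
    transcripts: Sequence[Transcript], path: "str | Path", width: int = 70
) -> None:
    with _open_text(path, "wt") as fh:
        for tr in transcripts:
            header = tr.gene_id if not tr.description else f"{tr.gene_id} {tr.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(tr.sequence), width):
                fh.write(tr.sequence[i : i + width] + "\n")


def read_fastq(path: "str | Path") -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from FASTQ; gzip handled by extension.

    Quality strings are parsed (and length-checked by the parser) but not
    used.  A truncated or malformed record raises an error naming the
    1-based record index at which parsing failed.
    """
    record = 0
    with _open_text(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, _qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed FASTQ at record {record + 1}: {exc}"
                ) from exc
            record += 1
            yield title.split(None, 1)[0], seq.upper()


def write_fastq(
    reads: Iterable[tuple[str, str]], path: "str | Path", quality_char: str = "I"
) -> int:
    """Write (read_id, sequence) pairs as FASTQ with constant quality."""
    n = 0
    with _open_text(path, "wt") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


def write_profile(profile: TagCountProfile, path: "str | Path") -> None:
    """Persist a profile as TSV: tag, count[, tpm].

    Rows are ordered by descending count, ties broken by tag sequence, so
    output is deterministic and the most abundant tags lead the file.
    """
    with_tpm = profile.normalized is not None
    with _open_text(path, "wt") as fh:
        fh.write(f"# sample_id={profile.sample_id}\n")
        if profile.enzyme is not None:
            fh.write(f"# enzyme={profile.enzyme.name}\n")
        fh.write("tag\tcount\ttpm\n" if with_tpm else "tag\tcount\n")
        for tag, count in sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0])):
            if with_tpm:
                fh.write(f"{tag}\t{count}\t{profile.normalized[tag]:.6f}\n")
            else:
                fh.write(f"{tag}\t{count}\n")


def read_profile(
    path: "str | Path",
    sample_id: str | None = None,
    enzyme: "AnchoringEnzyme | str | None" = None,
) -> TagCountProfile:
    """Read a profile TSV back; '# key=value' comments restore metadata.

    Explicit ``sample_id``/``enzyme`` arguments override file metadata.
    Malformed lines raise with their line number.
    """
    counts: dict[str, int] = {}
    normalized: dict[str, float] = {}
    has_tpm = False
    meta: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split("\t")
            if parts[0] == "tag":
                has_tpm = len(parts) > 2 and parts[2] == "tpm"
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected tag<TAB>count")
            tag = parts[0]
            if tag in counts:
                raise ValueError(f"{path}: line {lineno}: duplicate tag {tag!r}")
            try:
                counts[tag] = int(parts[1])
                if has_tpm:
                    normalized[tag] = float(parts[2])
            except (ValueError, IndexError):
                raise ValueError(
                    f"{path}: line {lineno}: malformed count/tpm fields"
                ) from None
    if sample_id is None:
        sample_id = meta.get("sample_id", Path(path).stem)
    if enzyme is None and "enzyme" in meta:
        enzyme = meta["enzyme"]
    return TagCountProfile(
        sample_id=sample_id,
        enzyme=None if enzyme is None else get_enzyme(enzyme),
        counts=counts,
        normalized=normalized if has_tpm else None,
    )


def write_stats(stats: ExtractionStats, path: "str | Path") -> None:
    with _open_text(path, "wt") as fh:
        json.dump(stats.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_virtual_tag_index(index: VirtualTagIndex, path: "str | Path") -> None:
    """TSV: tag, enzyme, gene_ids (comma-joined), ambiguous(0/1), padded(0/1).

    ``padded`` is 1 when any of the tag's genes needed poly-A padding.
    Siteless genes are listed in trailing comment lines.
    """
    padded_tags = {
        tag for gene, (tag, padded) in index.gene_tags.items() if padded
    }
    with _open_text(path, "wt") as fh:
        fh.write("tag\tenzyme\tgene_ids\tambiguous\tpadded\n")
        for tag in sorted(index.entries):
            genes = ",".join(sorted(index.entries[tag]))
            amb = int(tag in index.ambiguous)
            pad = int(tag in padded_tags)
            fh.write(f"{tag}\t{index.enzyme.name}\t{genes}\t{amb}\t{pad}\n")
        for gene in index.siteless:
            fh.write(f"# siteless\t{gene}\n")


def write_truth(truth: SimulationTruth, path: "str | Path") -> None:
    """Per-read truth ledger TSV: read_id, sample_id, gene_id, raw_length."""
    with _open_text(path, "wt") as fh:
        fh.write("read_id\tsample_id\tgene_id\traw_length\n")
        for read_id in sorted(truth.provenance):
            p = truth.provenance[read_id]
            fh.write(f"{p.read_id}\t{p.sample_id}\t{p.gene_id}\t{p.raw_length}\n")


def read_truth(path: "str | Path") -> dict[str, ReadProvenance]:
    prov: dict[str, ReadProvenance] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("read_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            prov[parts[0]] = ReadProvenance(
                read_id=parts[0],
                sample_id=parts[1],
                gene_id=parts[2],
                raw_length=int(parts[3]),
            )
    return prov
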