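"""Anchoring enzymes and virtual tag derivation.

A SuperSAGE tag is anchored at the recognition site of a 4-base-cutter
("anchoring enzyme") closest to the poly-A tail of a transcript.  Given a
reference transcript set, the tag each gene *would* produce can be predicted
in silico ("virtual tag"): locate the 3'-most recognition site on the sense
strand and read the site plus the downstream bases toward the poly-A tail.
This module models the enzymes, performs the virtual digestion, builds the
tag -> gene lookup used for tag-to-gene mapping, and provides the site-census
and combined-coverage arithmetic used to reason about how many genes a set of
anchoring enzymes can monitor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "AnchoringEnzyme",
    "Transcript",
    "CanonicalTag",
    "VirtualTagIndex",
    "NLAIII",
    "DPNII",
    "BFAI",
    "BUILTIN_ENZYMES",
    "get_enzyme",
    "reverse_complement",
    "find_3prime_most_site",
    "extract_virtual_tag",
    "build_virtual_tag_index",
    "missing_site_census",
    "combined_coverage",
]

DNA_ALPHABET = frozenset("ACGT")
DNA_ALPHABET_N = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Standard tag length: anchoring site (4 bp) + 22 transcript bases.
TAG_LENGTH = 26


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}; N maps to N."""
    if not DNA_ALPHABET_N.issuperset(seq):
        bad = sorted(set(seq) - DNA_ALPHABET_N)
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnchoringEnzyme:
    """A 4-base-cutter restriction enzyme that anchors the tag position."""

    name: str
    site: str

    def __post_init__(self) -> None:
        if len(self.site) != 4 or not DNA_ALPHABET.issuperset(self.site):
            raise ValueError(
                f"recognition site must be 4 bases over A/C/G/T, got {self.site!r}"
            )

    @property
    def site_rc(self) -> str:
        """Recognition site in reverse-complement (read) orientation."""
        return reverse_complement(self.site)


NLAIII = AnchoringEnzyme("NlaIII", "CATG")
DPNII = AnchoringEnzyme("DpnII", "GATC")
BFAI = AnchoringEnzyme("BfaI", "CTAG")

BUILTIN_ENZYMES: dict[str, AnchoringEnzyme] = {
    e.name: e for e in (NLAIII, DPNII, BFAI)
}
_BUILTIN_LOWER = {name.lower(): enz for name, enz in BUILTIN_ENZYMES.items()}


def get_enzyme(enzyme: "AnchoringEnzyme | str") -> AnchoringEnzyme:
    """Resolve an enzyme object or a (case-insensitive) built-in name."""
    if isinstance(enzyme, AnchoringEnzyme):
        return enzyme
    try:
        return _BUILTIN_LOWER[str(enzyme).lower()]
    except KeyError:
        raise KeyError(
            f"unknown anchoring enzyme {enzyme!r}; "
            f"built-ins are {sorted(BUILTIN_ENZYMES)}"
        ) from None


@dataclass(frozen=True)
class Transcript:
    """A sense-strand cDNA sequence (5'->3', poly-A tail optional)."""

    gene_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: sequence must be non-empty")
        if not DNA_ALPHABET_N.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - DNA_ALPHABET_N)
            raise ValueError(f"{self.gene_id}: non-DNA characters {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CanonicalTag:
    """A fixed-length tag beginning with its anchoring enzyme's site.

    ``padded`` marks tags whose transcript ended fewer than (length - 4)
    bases after the site; the remainder is filled with A, continuing into
    the poly-A tail as in the molecule.
    """

    sequence: str
    enzyme: AnchoringEnzyme
    padded: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) < 5:
            raise ValueError("tag must be longer than the anchoring site")
        if not DNA_ALPHABET.issuperset(self.sequence):
            raise ValueError(f"tag contains non-ACGT characters: {self.sequence!r}")
        if not self.sequence.startswith(self.enzyme.site):
            raise ValueError(
                f"tag {self.sequence!r} does not start with "
                f"{self.enzyme.name} site {self.enzyme.site}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def find_3prime_most_site(
    transcript: "Transcript | str", enzyme: "AnchoringEnzyme | str"
) -> int | None:
    """1-based start of the last (3'-most) occurrence of the site, or None.

    The search runs on the sense strand only: the protocol anchors to the
    mRNA 3' end, so reverse-strand sites are irrelevant.  N never matches.
    """
    enzyme = get_enzyme(enzyme)
    seq = transcript.sequence if isinstance(transcript, Transcript) else transcript
    pos = seq.rfind(enzyme.site)
    return None if pos < 0 else pos + 1


def extract_virtual_tag(
    transcript: Transcript,
    enzyme: "AnchoringEnzyme | str",
    tag_length: int = TAG_LENGTH,
) -> CanonicalTag | None:
    """Predict the tag a transcript yields: site + downstream bases.

    Returns None when the transcript has no recognition site.  If fewer than
    ``tag_length - 4`` bases remain downstream of the 3'-most site, the tag is
    completed with A (poly-A continuation) and flagged ``padded``.
    """
    if tag_length < 5:
        raise ValueError("tag_length must be at least 5 (site + 1 base)")
    enzyme = get_enzyme(enzyme)
    pos = find_3prime_most_site(transcript, enzyme)
    if pos is None:
        return None
    start = pos - 1  # back to 0-based
    downstream = transcript.sequence[start + 4 : start + tag_length]
    if "N" in downstream:
        # an N inside the tag window leaves the tag undefined; no tag
        return None
    padded = len(downstream) < tag_length - 4
    body = downstream + "A" * (tag_length - 4 - len(downstream))
    return CanonicalTag(enzyme.site + body, enzyme, padded=padded)


@dataclass
class VirtualTagIndex:
    """Exact-match lookup from virtual tag sequence to the genes yielding it."""

    enzyme: AnchoringEnzyme
    entries: dict[str, list[str]] = field(default_factory=dict)
    ambiguous: set[str] = field(default_factory=set)
    #: gene_id -> (tag sequence, padded flag), for genes with a site
    gene_tags: dict[str, tuple[str, bool]] = field(default_factory=dict)
    #: genes with no recognition site, in input order
    siteless: list[str] = field(default_factory=list)

    def genes_for(self, tag: str) -> list[str]:
        return self.entries.get(tag, [])

    def __contains__(self, tag: str) -> bool:
        return tag in self.entries


def build_virtual_tag_index(
    transcripts: Sequence[Transcript],
    enzyme: "AnchoringEnzyme | str",
    tag_length: int = TAG_LENGTH,
) -> VirtualTagIndex:
    """Virtually digest a transcript set into a tag -> gene index.

    Tags shared by more than one gene are kept in the index but recorded in
    ``ambiguous`` so downstream per-gene attribution can skip them.
    """
    enzyme = get_enzyme(enzyme)
    seen: set[str] = set()
    index = VirtualTagIndex(enzyme=enzyme)
    for tr in transcripts:
        if tr.gene_id in seen:
            raise ValueError(f"duplicate gene_id {tr.gene_id!r} in transcript set")
        seen.add(tr.gene_id)
        tag = extract_virtual_tag(tr, enzyme, tag_length)
        if tag is None:
            index.siteless.append(tr.gene_id)
            continue
        index.gene_tags[tr.gene_id] = (tag.sequence, tag.padded)
        index.entries.setdefault(tag.sequence, []).append(tr.gene_id)
    index.ambiguous = {t for t, genes in index.entries.items() if len(genes) > 1}
    return index


def missing_site_census(
    transcripts: Sequence[Transcript],
    enzymes: Iterable["AnchoringEnzyme | str"],
) -> dict[str, tuple[int, float]]:
    """Per-enzyme (count, fraction) of genes lacking the recognition site."""
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("transcript set is empty")
    total = len(transcripts)
    result: dict[str, tuple[int, float]] = {}
    for enz in enzymes:
        enz = get_enzyme(enz)
        missing = sum(
            1 for tr in transcripts if find_3prime_most_site(tr, enz) is None
        )
        result[enz.name] = (missing, missing / total)
    return result


def combined_coverage(missing_rates: Sequence[float]) -> float:
    """Fraction of genes monitored by at least one enzyme.

    Assumes site absence is independent across enzymes, so the uncovered
    fraction is the product of the per-enzyme missing rates:
    coverage = 1 - prod(rates).
    """
    if not missing_rates:
        raise ValueError("need at least one missing rate")
    prod = 1.0
    for r in missing_rates:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"missing rate {r} outside [0, 1]")
        prod *= r
    return 1.0 - prod
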