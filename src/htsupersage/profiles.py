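"""Tag-count profiles and expression analytics.

A library's expression profile is a map from canonical 26-bp tag to its
observed count.  This module provides the count-level operations: library
summaries (total / unique / non-singleton tags), tags-per-million
normalization, post-hoc tag filters (homopolymer runs, reference match),
pairwise R-squared reproducibility comparisons, the per-gene multi-enzyme
expression table, and the "missing transcript" statistic -- for a given
anchoring enzyme, a gene whose tag count falls below 10% of its mean
abundance across enzymes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scistats

from .enzymes import (
    AnchoringEnzyme,
    Transcript,
    VirtualTagIndex,
    reverse_complement,
)

__all__ = [
    "TagCountProfile",
    "ProfileSummary",
    "PairwiseR2",
    "GeneEnzymeTable",
    "MissingTranscriptReport",
    "profile_summary",
    "normalize_tpm",
    "longest_homopolymer_run",
    "filter_homopolymer",
    "filter_by_reference",
    "pairwise_r2",
    "gene_expression_table",
    "missing_transcript_analysis",
]

TPM_SCALE = 1_000_000


@dataclass
class TagCountProfile:
    """Per-sample tag -> count map, optionally with TPM normalization."""

    sample_id: str
    enzyme: AnchoringEnzyme | None
    counts: dict[str, int]
    normalized: dict[str, float] | None = None

    def total(self) -> int:
        return sum(self.counts.values())

    def validate(self) -> None:
        """Check tag shape invariants (26 bp, enzyme-site prefix)."""
        for tag in self.counts:
            if len(tag) != 26:
                raise ValueError(f"{self.sample_id}: tag {tag!r} is not 26 bp")
            if self.enzyme is not None and not tag.startswith(self.enzyme.site):
                raise ValueError(
                    f"{self.sample_id}: tag {tag!r} lacks "
                    f"{self.enzyme.name} site prefix"
                )
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"{self.sample_id}: negative count")


class ProfileSummary(NamedTuple):
    total_tags: int
    unique_tags: int
    non_singleton_tags: int


def profile_summary(profile: TagCountProfile) -> ProfileSummary:
    """Library-size summary: total tag count, distinct tags, tags seen >= 2x."""
    counts = profile.counts.values()
    return ProfileSummary(
        total_tags=sum(counts),
        unique_tags=len(profile.counts),
        non_singleton_tags=sum(1 for c in counts if c >= 2),
    )


def normalize_tpm(profile: TagCountProfile) -> TagCountProfile:
    """Tags-per-million: count * 1e6 / library total.  Requires total > 0."""
    total = profile.total()
    if total == 0:
        raise ValueError(f"{profile.sample_id}: cannot normalize an empty profile")
    normalized = {t: c * TPM_SCALE / total for t, c in profile.counts.items()}
    return replace(profile, normalized=normalized)


def longest_homopolymer_run(seq: str) -> int:
    """Length of the longest single-base run in ``seq`` (0 for empty)."""
    best = run = 0
    prev = None
    for base in seq:
        run = run + 1 if base == prev else 1
        prev = base
        best = max(best, run)
    return best


def filter_homopolymer(
    profile: TagCountProfile, max_run: int = 5
) -> tuple[TagCountProfile, list[str]]:
    """Remove tags containing a single-base run strictly longer than max_run.

    Homopolymer-bearing tags are error-prone in some sequencing chemistries;
    the default keeps runs of up to 5 and removes >5.
    """
    if max_run < 1:
        raise ValueError("max_run must be >= 1")
    removed = sorted(
        t for t in profile.counts if longest_homopolymer_run(t) > max_run
    )
    removed_set = set(removed)
    retained = replace(
        profile,
        counts={t: c for t, c in profile.counts.items() if t not in removed_set},
        normalized=None
        if profile.normalized is None
        else {t: v for t, v in profile.normalized.items() if t not in removed_set},
    )
    return retained, removed


def filter_by_reference(
    profile: TagCountProfile,
    reference: "Sequence[Transcript] | VirtualTagIndex",
    mode: str = "substring",
) -> tuple[TagCountProfile, list[str]]:
    """Keep only tags supported by a reference.

    mode="substring": the tag occurs verbatim in some reference sequence on
    either strand.  mode="virtual_index": the tag is a key of a
    VirtualTagIndex (exact virtual-tag match).
    """
    if mode not in ("substring", "virtual_index"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "virtual_index":
        if not isinstance(reference, VirtualTagIndex):
            raise TypeError("virtual_index mode needs a VirtualTagIndex")
        keep = lambda tag: tag in reference.entries
    else:
        seqs = [
            tr.sequence if isinstance(tr, Transcript) else str(tr)
            for tr in reference
        ]
        if not seqs:
            raise ValueError("reference is empty")

        def keep(tag: str) -> bool:
            rc = reverse_complement(tag)
            return any(tag in s or rc in s for s in seqs)

    removed = sorted(t for t in profile.counts if not keep(t))
    removed_set = set(removed)
    retained = replace(
        profile,
        counts={t: c for t, c in profile.counts.items() if t not in removed_set},
        normalized=None
        if profile.normalized is None
        else {t: v for t, v in profile.normalized.items() if t not in removed_set},
    )
    return retained, removed


class PairwiseR2(NamedTuple):
    r2: float
    r: float
    n_tags: int


def pairwise_r2(
    a: TagCountProfile, b: TagCountProfile, scale: str = "raw"
) -> PairwiseR2:
    """Squared Pearson correlation of two profiles over their tag union.

    Tags absent from one profile count as 0 there.  scale="log10p1" applies
    log10(count + 1) first.  The signed r is reported alongside r^2 since
    r^2 alone hides anticorrelation.  Zero variance in either vector leaves
    the correlation undefined and raises.
    """
    if scale not in ("raw", "log10p1"):
        raise ValueError(f"unknown scale {scale!r}")
    tags = sorted(set(a.counts) | set(b.counts))
    if not tags:
        raise ValueError("both profiles are empty")
    x = np.array([a.counts.get(t, 0) for t in tags], dtype=float)
    y = np.array([b.counts.get(t, 0) for t in tags], dtype=float)
    if scale == "log10p1":
        x = np.log10(x + 1.0)
        y = np.log10(y + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance profile: correlation undefined")
    r = float(_scistats.pearsonr(x, y).statistic)
    return PairwiseR2(r2=r * r, r=r, n_tags=len(tags))


@dataclass
class GeneEnzymeTable:
    """Per-gene TPM by anchoring enzyme, plus mean abundance.

    ``table`` is indexed by gene_id with one TPM column per enzyme name and
    an ``abundance`` column equal to the arithmetic mean of the per-enzyme
    TPMs (enzymes without a site or without counts contribute 0).
    """

    table: pd.DataFrame
    enzymes: list[str]

    def __len__(self) -> int:
        return len(self.table)


def gene_expression_table(
    profiles: Sequence[TagCountProfile],
    indexes: Sequence[VirtualTagIndex],
) -> GeneEnzymeTable:
    """Map each enzyme's normalized profile onto genes via its virtual tags.

    A gene's TPM under an enzyme is the TPM of its (unambiguous) virtual tag
    in that enzyme's profile; ambiguous tags are skipped and absent tags are
    0.  Profiles must be normalized and paired 1:1 with indexes of the same
    enzyme.
    """
    if len(profiles) != len(indexes):
        raise ValueError("need one profile per virtual-tag index")
    enzymes: list[str] = []
    for p, ix in zip(profiles, indexes):
        if p.enzyme is None or p.enzyme.name != ix.enzyme.name:
            raise ValueError(
                f"profile {p.sample_id} enzyme does not match index enzyme "
                f"{ix.enzyme.name}"
            )
        if p.normalized is None:
            raise ValueError(f"profile {p.sample_id} is not normalized")
        enzymes.append(ix.enzyme.name)
    if len(set(enzymes)) != len(enzymes):
        raise ValueError("duplicate enzyme among profiles")

    genes: set[str] = set()
    for ix in indexes:
        genes.update(ix.gene_tags)
        genes.update(ix.siteless)
    gene_list = sorted(genes)

    data: dict[str, list[float]] = {}
    for p, ix in zip(profiles, indexes):
        col = []
        for g in gene_list:
            rec = ix.gene_tags.get(g)
            if rec is None or rec[0] in ix.ambiguous:
                col.append(0.0)
            else:
                col.append(p.normalized.get(rec[0], 0.0))
        data[ix.enzyme.name] = col
    df = pd.DataFrame(data, index=pd.Index(gene_list, name="gene_id"))
    df["abundance"] = df[enzymes].mean(axis=1)
    return GeneEnzymeTable(table=df, enzymes=enzymes)


@dataclass
class MissingTranscriptReport:
    """Per-enzyme missing counts among the top_n most abundant genes."""

    missing_counts: dict[str, int]
    flags: pd.DataFrame  # top_n genes x enzymes, True where missing
    top_n: int
    threshold: float


def missing_transcript_analysis(
    table: GeneEnzymeTable,
    top_n: int = 1000,
    threshold: float = 0.1,
) -> MissingTranscriptReport:
    """Count missing transcripts per enzyme among the top_n abundant genes.

    Genes are ranked by mean abundance (descending; ties broken by gene_id;
    zero-abundance genes excluded).  A gene is missing for an enzyme when its
    TPM under that enzyme is below ``threshold`` times its abundance.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    df = table.table[table.table["abundance"] > 0]
    if top_n > len(df):
        raise ValueError(
            f"top_n={top_n} exceeds the {len(df)} genes with nonzero abundance"
        )
    ranked = df.sort_values(
        by=["abundance", "gene_id"], ascending=[False, True], kind="mergesort"
    ).head(top_n)
    flags = ranked[table.enzymes].lt(
        ranked["abundance"] * threshold, axis=0
    )
    counts = {e: int(flags[e].sum()) for e in table.enzymes}
    return MissingTranscriptReport(
        missing_counts=counts, flags=flags, top_n=top_n, threshold=threshold
    )
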