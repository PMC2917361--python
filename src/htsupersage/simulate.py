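"""In-silico library preparation and sequencing.

The simulator emulates the indexed tag-library prep end to end: a synthetic
transcriptome with controlled recognition-site presence, lognormal expression
weights, tag release at the 3'-most anchoring site with a variable cut length
(26-31 nt, mode 27 -- the type III tagging enzyme cuts at a variable
distance), adapter ligation, 4-bp sample indexing, pooling, and 35-nt
sequencing with independent per-base substitution errors in the index and tag
regions.  Every emitted read is recorded in a truth ledger (source library,
source gene, intended raw length) so demultiplexing and counting can be
validated by exact recovery, and cross-sample contamination can be measured
from provenance rather than inferred.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .demux import BarcodeTable, ExtractionConfig, classify_read
from .enzymes import (
    DNA_ALPHABET,
    AnchoringEnzyme,
    Transcript,
    extract_virtual_tag,
    get_enzyme,
    reverse_complement,
)

__all__ = [
    "ADAPTER2_BOTTOM",
    "DEFAULT_TAG_LENGTH_DISTRIBUTION",
    "LibrarySpec",
    "ReadProvenance",
    "SimulationTruth",
    "simulate_transcriptome",
    "simulate_expression",
    "construct_read",
    "simulate_library",
    "simulate_multiplexed_run",
    "measure_contamination",
]

#: Adapter-2 bottom-strand oligo; its 5' end abuts the tag in the read, so
#: reads shorter than index + 31 are filled with this prefix.
ADAPTER2_BOTTOM = "CTGCTGCGTACATCGTTAGATCGTATGCCGTCTTCTGCTTG"

#: Raw tag length probabilities: the 27/26 shares are the observed modal
#: values (66% / 25%); the residual 9% is spread over 28-31.
DEFAULT_TAG_LENGTH_DISTRIBUTION: dict[int, float] = {
    26: 0.25,
    27: 0.66,
    28: 0.04,
    29: 0.03,
    30: 0.01,
    31: 0.01,
}

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass(frozen=True)
class LibrarySpec:
    """Parameters of one simulated indexed library."""

    sample_id: str
    index: str
    enzyme: AnchoringEnzyme
    n_reads: int
    tag_length_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_TAG_LENGTH_DISTRIBUTION)
    )
    index_substitution_rate: float = 0.0
    tag_substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.index) != 4 or not DNA_ALPHABET.issuperset(self.index):
            raise ValueError(f"malformed index {self.index!r}")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        total = sum(self.tag_length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tag length probabilities sum to {total}, not 1")
        for length in self.tag_length_distribution:
            if not 26 <= length <= 31:
                raise ValueError(f"raw tag length {length} outside 26-31")
        for rate in (self.index_substitution_rate, self.tag_substitution_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"substitution rate {rate} outside [0, 1]")


@dataclass(frozen=True)
class ReadProvenance:
    read_id: str
    sample_id: str
    gene_id: str
    raw_length: int


@dataclass
class SimulationTruth:
    """Ground truth of a simulated run, the oracle for recovery tests."""

    #: sample_id -> gene_id -> number of reads emitted
    per_library: dict[str, dict[str, int]] = field(default_factory=dict)
    #: read_id -> provenance, recorded before errors are applied
    provenance: dict[str, ReadProvenance] = field(default_factory=dict)
    #: sample_id -> gene_id -> true canonical 26-bp tag
    true_tags: dict[str, dict[str, str]] = field(default_factory=dict)

    def tag_counts(self, sample_id: str) -> dict[str, int]:
        """Expected canonical-tag counts for a library (genes sharing a
        virtual tag are merged, exactly as the demultiplexer would see them)."""
        counts: Counter = Counter()
        tags = self.true_tags[sample_id]
        for gene, n in self.per_library[sample_id].items():
            counts[tags[gene]] += n
        return dict(counts)

    def total_reads(self) -> int:
        return sum(sum(g.values()) for g in self.per_library.values())

    def merge(self, other: "SimulationTruth") -> None:
        overlap = set(self.per_library) & set(other.per_library)
        if overlap:
            raise ValueError(f"duplicate libraries in merge: {sorted(overlap)}")
        self.per_library.update(other.per_library)
        self.provenance.update(other.provenance)
        self.true_tags.update(other.true_tags)


def _random_body(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(_BASES, size=length))


def simulate_transcriptome(
    n_genes: int,
    length_range: tuple[int, int] = (300, 2000),
    site_presence: Mapping["AnchoringEnzyme | str", float] | None = None,
    polyA_length: int = 27,
    seed: int = 0,
    presence_matrix: "Sequence[Mapping[str, bool]] | None" = None,
) -> tuple[list[Transcript], list[dict[str, bool]]]:
    """Random transcripts with controlled recognition-site presence.

    Each gene carries each enzyme's site with the stated probability
    (independently per enzyme); sites are injected or scrubbed until the
    drawn pattern holds exactly.  ``presence_matrix`` (one {enzyme_name:
    bool} mapping per gene) overrides the random draw, for designed site
    patterns.  A poly-A tail of ``polyA_length`` A's is appended; the default
    of 27 (the longest cut extension beyond the site) guarantees every raw
    tag is a verbatim substring of its transcript, never artificially padded.
    Returns (transcripts, ledger) where ledger[i] maps enzyme name ->
    site present.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo < 31:
        raise ValueError("minimum transcript length must be >= 31 to host a tag")
    if hi < lo:
        raise ValueError("empty length range")
    if site_presence is None:
        site_presence = {e: 1.0 for e in ("NlaIII", "DpnII", "BfaI")}
    enzymes = {get_enzyme(e).name: get_enzyme(e) for e in site_presence}
    probs = {get_enzyme(e).name: p for e, p in site_presence.items()}
    for name, p in probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"site presence for {name} outside [0, 1]: {p}")
    if presence_matrix is not None and len(presence_matrix) != n_genes:
        raise ValueError("presence_matrix length must equal n_genes")

    rng = np.random.default_rng(seed)
    width = len(str(n_genes - 1))
    transcripts: list[Transcript] = []
    ledger: list[dict[str, bool]] = []

    for g in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        if presence_matrix is not None:
            want = {name: bool(presence_matrix[g].get(name, False)) for name in enzymes}
        else:
            want = {name: bool(rng.random() < probs[name]) for name in enzymes}
        body = _random_body(rng, length)
        for _ in range(200):
            changed = False
            seq = "".join(body)
            for name, enz in enzymes.items():
                if want[name]:
                    if enz.site not in seq:
                        # leave >= 27 bases downstream when the gene is long
                        # enough, so tags are rarely poly-A padded
                        hi_pos = max(1, length - 30)
                        pos = int(rng.integers(0, hi_pos))
                        body[pos : pos + 4] = list(enz.site)
                        changed = True
                else:
                    start = seq.find(enz.site)
                    while start != -1:
                        off = int(rng.integers(0, 4))
                        old = body[start + off]
                        choices = [b for b in "ACGT" if b != old]
                        body[start + off] = choices[int(rng.integers(0, 3))]
                        seq = "".join(body)
                        start = seq.find(enz.site)
                        changed = True
            if not changed:
                break
        else:  # pragma: no cover - repair loop converges in practice
            raise RuntimeError(f"could not satisfy site pattern for gene {g}")
        seq = "".join(body) + "A" * polyA_length
        gene_id = f"gene{g:0{width}d}"
        transcripts.append(Transcript(gene_id=gene_id, sequence=seq))
        ledger.append(dict(want))
    return transcripts, ledger


def simulate_expression(
    n_genes: int, lognormal_sigma: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Per-gene sampling weights, lognormal and normalized to sum 1.

    sigma is the standard deviation of the natural-log weight; sigma = 0
    gives uniform weights.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if lognormal_sigma < 0:
        raise ValueError("lognormal_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if lognormal_sigma == 0:
        return np.full(n_genes, 1.0 / n_genes)
    w = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=n_genes)
    return w / w.sum()


def construct_read(
    tag_sequence: str,
    raw_length: int,
    index: str,
    read_length: int = 35,
) -> str:
    """Assemble one error-free read from a tag.

    read = index + reverse_complement(raw tag) + adapter-2 bottom-strand
    prefix, truncated to ``read_length``.  The raw tag is the given tag
    extended with A to ``raw_length`` if needed (a longer cut runs toward the
    poly-A tail; callers that know the source transcript should pass the
    re-extracted site + (raw_length - 4) bases instead).
    """
    if not 26 <= raw_length <= 31:
        raise ValueError(f"raw_length {raw_length} outside 26-31")
    if len(index) != 4 or not DNA_ALPHABET.issuperset(index):
        raise ValueError(f"malformed index {index!r}")
    raw_tag = tag_sequence[:raw_length]
    raw_tag += "A" * (raw_length - len(raw_tag))
    read = index + reverse_complement(raw_tag) + ADAPTER2_BOTTOM
    return read[:read_length]


def _mutate(
    seq: list[str], start: int, stop: int, rate: float, rng: np.random.Generator
) -> None:
    """Apply per-base substitutions (always to a different base) in place."""
    n = stop - start
    if n <= 0:
        return
    hits = np.nonzero(rng.random(n) < rate)[0]
    for h in hits:
        i = start + int(h)
        old = seq[i]
        choices = [b for b in "ACGT" if b != old]
        seq[i] = choices[int(rng.integers(0, 3))]


def simulate_library(
    spec: LibrarySpec,
    transcripts: Sequence[Transcript],
    weights: np.ndarray,
    read_length: int = 35,
) -> tuple[list[tuple[str, str]], SimulationTruth]:
    """Simulate one indexed library; returns (reads, truth ledger).

    Genes are sampled with replacement by expression weight, restricted to
    genes carrying the enzyme's site (siteless genes drop out of the library,
    which is the molecular origin of the missing-transcript phenomenon).  Raw
    lengths are drawn from the spec's distribution; the raw tag is
    re-extracted from the source transcript at that length.  Substitution
    errors hit index and tag bases independently; the truth ledger records
    pre-error provenance.
    """
    if len(weights) != len(transcripts):
        raise ValueError("weights and transcripts differ in length")
    rng = np.random.default_rng(spec.seed)

    eligible: list[int] = []
    ext_rc: list[str] = []  # reverse complement of site + 27 downstream bases
    true_tag: list[str] = []
    for i, tr in enumerate(transcripts):
        tag31 = extract_virtual_tag(tr, spec.enzyme, tag_length=31)
        if tag31 is None:
            continue
        eligible.append(i)
        ext_rc.append(reverse_complement(tag31.sequence))
        true_tag.append(tag31.sequence[:26])
    if not eligible:
        raise ValueError(
            f"{spec.sample_id}: no transcript carries the "
            f"{spec.enzyme.name} site"
        )

    w = np.asarray([weights[i] for i in eligible], dtype=float)
    w = w / w.sum()
    lengths = np.array(sorted(spec.tag_length_distribution), dtype=int)
    probs = np.array(
        [spec.tag_length_distribution[int(l)] for l in lengths], dtype=float
    )
    probs = probs / probs.sum()

    gene_draws = rng.choice(len(eligible), size=spec.n_reads, p=w)
    length_draws = lengths[rng.choice(len(lengths), size=spec.n_reads, p=probs)]

    mutate = spec.index_substitution_rate > 0 or spec.tag_substitution_rate > 0
    reads: list[tuple[str, str]] = []
    counts: dict[str, int] = {}
    prov: dict[str, ReadProvenance] = {}
    width = len(str(max(spec.n_reads - 1, 0)))
    for k in range(spec.n_reads):
        gi = int(gene_draws[k])
        raw_len = int(length_draws[k])
        gene = transcripts[eligible[gi]]
        # rc(raw tag) is a suffix of rc(31-base extended tag)
        read = spec.index + ext_rc[gi][31 - raw_len :] + ADAPTER2_BOTTOM
        read = read[:read_length]
        if mutate:
            chars = list(read)
            _mutate(chars, 0, 4, spec.index_substitution_rate, rng)
            _mutate(
                chars,
                4,
                min(4 + raw_len, len(chars)),
                spec.tag_substitution_rate,
                rng,
            )
            read = "".join(chars)
        read_id = f"{spec.sample_id}:{k:0{width}d}"
        reads.append((read_id, read))
        counts[gene.gene_id] = counts.get(gene.gene_id, 0) + 1
        prov[read_id] = ReadProvenance(
            read_id=read_id,
            sample_id=spec.sample_id,
            gene_id=gene.gene_id,
            raw_length=raw_len,
        )

    truth = SimulationTruth(
        per_library={spec.sample_id: counts},
        provenance=prov,
        true_tags={
            spec.sample_id: {
                transcripts[i].gene_id: t for i, t in zip(eligible, true_tag)
            }
        },
    )
    return reads, truth


def simulate_multiplexed_run(
    specs: Sequence[LibrarySpec],
    transcripts: Sequence[Transcript],
    weights: np.ndarray,
    seed: int = 0,
    read_length: int = 35,
) -> tuple[list[tuple[str, str]], SimulationTruth]:
    """Simulate several libraries, pool them and shuffle the read order.

    Indexes must be unique across specs (pooled libraries share one lane, so
    the index alone identifies the library).  The shuffle is seeded, making
    the pooled output byte-reproducible.
    """
    indexes = [s.index for s in specs]
    if len(set(indexes)) != len(indexes):
        raise ValueError("duplicate index across library specs")
    pooled: list[tuple[str, str]] = []
    truth = SimulationTruth()
    for spec in specs:
        reads, t = simulate_library(spec, transcripts, weights, read_length)
        pooled.extend(reads)
        truth.merge(t)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pooled))
    pooled = [pooled[i] for i in order]
    return pooled, truth


def measure_contamination(
    reads: Iterable[tuple[str, str]],
    table: BarcodeTable,
    truth: SimulationTruth,
    config: ExtractionConfig | None = None,
) -> tuple[float, int, int]:
    """Provenance-based cross-sample contamination of a simulated run.

    Classifies every read and compares the assigned sample with the true
    source library.  Returns (fraction, misassigned, classified); the
    fraction is misassigned / classified (0.0 when nothing classifies).
    """
    config = config or ExtractionConfig()
    classified = 0
    wrong = 0
    for read_id, seq in reads:
        cls = classify_read(seq, table, config)
        if not cls.classified:
            continue
        classified += 1
        if cls.sample_id != truth.provenance[read_id].sample_id:
            wrong += 1
    fraction = wrong / classified if classified else 0.0
    return fraction, wrong, classified
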