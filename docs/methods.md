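# Methods

## Read model and tag extraction

A sequencing read is modelled as a fixed-layout 35-nt string: a 4-bp sample
index, then the raw tag in reverse-complement orientation, then as much of
the adapter-2 bottom strand (`CTGCTGCGTACATCGTTAGATCGTATGCCGTCTTCTGCTTG`) as
fits. The raw tag spans read positions 5 through the end of the anchoring
enzyme's recognition site; because the tag was ligated in inverted
orientation, the site is matched as its reverse complement at the tag's 3'
end. All three built-in sites (NlaIII `CATG`, DpnII `GATC`, BfaI `CTAG`) are
palindromic, so the reverse-complement rule is invisible for them, but it is
applied explicitly so that non-palindromic cutters would be handled
correctly.

Classification of a read proceeds in a fixed order of rejection reasons:

1. `too_short` — shorter than index + minimum raw tag (default 4 + 26);
2. `contains_N` — an N inside the index region;
3. `unknown_index` — the first 4 bases match no barcode-table index
   (matching is exact; the protocol's barcode spacing makes single-base
   index errors rare enough to tolerate rather than correct);
4. per-enzyme site search. A candidate is an in-range raw tag (26–31 nt by
   default) terminated by the reverse-complemented site. Among several
   candidates the **longest wins**: the genuine site abuts adapter-2, i.e.
   it is the index-distal candidate. No candidate → `no_anchor_site`; when
   one index is shared by samples digested with different enzymes (the
   sub-library layout) and more than one enzyme yields a candidate, the
   read is `ambiguous`;
5. `contains_N` — an N inside the raw tag.

The ordering means an N that destroys the only possible site match is
reported as `no_anchor_site`, not `contains_N`; the conservation invariant
(`classified + Σ rejected = total`) holds regardless.

The canonical tag is `reverse_complement(raw tag)` truncated to its first 26
bases — the anchoring site plus the 22 site-proximal bases — so 27–31-nt cut
variants of the same transcript position collapse onto one counting unit.
The alternative (a fixed window at read positions 5–30) would split those
variants; the site-anchored rule was chosen because it merges them.

An optional adapter-confirmation mode additionally requires the bases after
a candidate site to match the adapter-2 bottom-strand prefix (`CTGCT`);
bases beyond the read end are not required. It is off by default because
the longest-candidate rule alone is already exact on simulated data.

A 1-mismatch index correction was considered and rejected: the reference
27-index set has minimum pairwise Hamming distance 1, so any correction
would misassign reads between real samples. `barcode_distance_audit`
reports the minimum pairwise distance and all distance-1 pairs so users can
judge their own index sets; exact matching is the default and only mode.

## Virtual tags and coverage arithmetic

Virtual digestion takes the **last** (3'-most) occurrence of the site on
the sense strand only — the protocol anchors at the site closest to the
poly-A tail, and reverse-strand sites play no role. N never matches a site.
If fewer than 22 bases follow the site, the tag is completed with A
(continuing into the poly-A tail, as in the molecule) and flagged `padded`;
if an N falls inside the tag window the gene yields no defined tag.
Coordinates in all reports are 1-based inclusive.

Tags shared by several genes are kept in the index but marked ambiguous and
excluded from per-gene attribution, which avoids double counting at the
cost of dropping a small number of genes (none, in practice, for random
synthetic transcriptomes at 26-bp tag length).

Combined coverage of an enzyme panel is `1 − ∏ missing_rates`, assuming
site absence is independent across enzymes. That independence is an
approximation (GC-rich genes are depleted for AT-rich sites jointly), so
the number is an upper-bound-flavoured estimate, matching its use as a
back-of-envelope panel-design statistic.

## Profiles and statistics

* TPM normalization: `count × 10⁶ / library total`; computed **before**
  homopolymer/reference filtering, which are post-hoc re-analyses.
* Homopolymer filter: a tag is removed iff it contains a single-base run
  strictly longer than `max_run` (default 5).
* Reference filter: `substring` mode keeps tags occurring verbatim in any
  reference sequence on either strand; `virtual_index` mode keeps exact
  virtual-tag keys. Alignment-based mapping is deliberately out of scope.
* Pairwise R²: squared Pearson correlation over the **union** of tags with
  zero fill for absent tags, on raw counts by default (`log10p1`
  optional). The union convention is a choice — intersection would discard
  exactly the discordant tags the comparison should penalize. The signed r
  is reported alongside r² because r² alone hides anticorrelation.
  Zero-variance inputs make the statistic undefined and raise an error.
* Gene×enzyme table: a gene's TPM under an enzyme is the TPM of its
  unambiguous virtual tag (0 if the gene lacks a site, the tag is absent,
  or the tag is ambiguous). Abundance is the arithmetic mean of the
  per-enzyme TPMs **including zeros**; "mean of nonzero enzymes" was the
  other reading and would make a fully-missing enzyme invisible, defeating
  the statistic's purpose.
* Missing transcripts: rank genes by abundance (descending, ties broken
  lexicographically by gene_id, zero-abundance genes excluded), take the
  top `top_n` (default 1000), and flag gene×enzyme cells with
  `TPM < threshold × abundance` (default threshold 0.1). Missing counts are
  non-decreasing in the threshold.

## Simulator

The generator emulates the library prep, not the sequencer: substitution
errors only (no indels — an indel would shift the fixed read layout and is
not part of the error model this protocol's analysis needs), constant
quality scores, no PCR amplification bias (amplification at ≤10 cycles is
profile-neutral, which is why the protocol can use few cycles). Gene
sampling is multinomial with replacement from lognormal weights
(`sigma` on the natural log scale, default 1.0; sigma 0 gives uniform
weights). Genes without the library's anchoring site are excluded from
sampling — they simply yield no reads, which is the molecular origin of the
missing-transcript phenomenon.

Raw tag lengths are drawn from a configurable distribution, by default
`{26: 0.25, 27: 0.66, 28: 0.04, 29: 0.03, 30: 0.01, 31: 0.01}` — the
observed 27/26 shares with the residual 9% spread over 28–31. The raw tag
is re-extracted from the source transcript at the drawn length (not padded
from the 26-bp tag), so longer cuts carry genuine transcript sequence.

Synthetic transcripts are random-composition with per-enzyme site presence
controlled either probabilistically or by an explicit per-gene presence
matrix (for designed dropout patterns); sites are injected or scrubbed in a
seeded repair loop until the drawn pattern holds exactly. The poly-A tail
defaults to 27 A's — the longest cut extension beyond the site — so that
every simulated raw tag is a verbatim substring of its transcript and
poly-A padding never triggers for generator output (real 3'-UTRs end in
much longer tails; 27 is the shortest value with that guarantee). All
randomness flows from explicit integer seeds; identical seeds give
byte-identical FASTQ output.

The truth ledger records, per read and **before** errors are applied, the
source library, source gene and intended raw length. Recovery tests compare
demultiplexed counts against the ledger exactly (zero error rates) and
measure cross-sample contamination as the fraction of classified reads
assigned to a sample other than their source library.

### What the simulator does not capture

Real libraries add ligation biases, PCR duplicates, quality-dependent
miscalls, incomplete digestion and transcripts sharing 3' ends. Passing the
recovery tests therefore demonstrates the *algorithmic* correctness of
extraction, counting and the statistics — not that real-data artifact rates
are small; the filters exist precisely because real data needs them.

## Problem sizes

The validation suite uses desk-scale runs chosen to make the binomial error
of each estimated proportion much smaller than its tolerance: 100,000 reads
for the tag-length distribution (±1 percentage point checked; 2σ sampling
error ≈ 0.3), 27 × 5,000 reads for the multiplexed round trip, 4 × 15,000
reads per error rate for contamination monotonicity, and 1,000 genes ×
3 × 100,000 reads for missing-transcript recovery. In the recovery design
the site-absence categories are disjoint by construction (5.7% of genes
lack NlaIII only, 4.5% DpnII only, 20% BfaI only), for two reasons: every
gene then has nonzero abundance, so the full gene set can be ranked; and
with independent absences the recovered missing fraction among top-ranked
genes is systematically *below* the injected rate, because a gene lacking a
site genuinely has lower mean abundance and drops out of the top ranks —
a real confound of the statistic, not an implementation artifact, and the
designed construction isolates recovery correctness from it.

## Known limitations

* Exact-match tag→gene lookup only; no mismatch-tolerant mapping.
* The ambiguity rule discards shared virtual tags from per-gene counts
  rather than fractionally assigning them.
* The demultiplexer assumes the fixed single-end 35-nt layout; paired-end
  input and quality-based trimming are out of scope.
* Expression is simulated i.i.d. per read; overdispersion beyond
  multinomial sampling (biological replicate variance) is not modelled.
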