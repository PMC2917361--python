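# htsupersage

Indexed SuperSAGE digital gene expression analysis: demultiplexing of
bar-coded 35-nt tag reads, anchored 26-bp tag extraction and counting,
profile statistics, in-silico virtual-tag digestion of reference
transcripts, and a full library-prep simulator with ground-truth ledgers.

## The problem

SuperSAGE measures gene expression by counting short sequence *tags*, each
cut from a fixed position in a transcript: the recognition site of a 4-bp
anchoring enzyme (NlaIII `CATG`, DpnII `GATC` or BfaI `CTAG`) closest to the
poly-A tail. A type III tagging enzyme (EcoP15I) releases the tag at a
variable distance from its site, so raw tags run 26–31 nt with a mode of
27. In the multiplexed ("high-throughput") protocol, a 4-bp index on
adapter-1 identifies the sample, so many libraries are pooled in one
sequencing lane. Each 35-nt read is laid out as

```
[index (4)] [reverse-complemented raw tag (26–31)] [adapter-2 fill]
```

The computational tasks this package solves for people running or evaluating
such experiments:

* **Demultiplexing and tag extraction** — match the index exactly, find the
  anchoring site in reverse-complement orientation terminating the raw tag
  (longest in-range candidate wins), reverse-complement and standardize to a
  canonical 26-bp tag (`site + 22 bases`), and account for every read
  (`classified + rejected = total`).
* **Profile analytics** — per-library summaries, tags-per-million
  normalization (TPM = count × 10⁶ / total), homopolymer (>5-base run) and
  reference-match filters, and pairwise R² reproducibility comparisons over
  the tag union.
* **Virtual tags** — predict each gene's tag from a transcript FASTA, build
  an exact tag→gene index, census genes lacking each enzyme's site, and
  compute combined coverage `1 − ∏ missing_rates` for enzyme combinations.
* **Missing transcripts** — rank genes by mean TPM abundance across
  enzymes; a gene is *missing* for an enzyme when its tag's TPM falls below
  10% of that abundance. This quantifies which genes an anchoring enzyme
  cannot monitor.
* **Simulation** — generate a synthetic transcriptome with controlled site
  presence, lognormal expression, the empirical cut-length distribution
  (27 nt: 66%, 26 nt: 25%), substitution errors in index and tag, and a
  per-read truth ledger, so every stage can be validated by exact recovery
  and contamination can be *measured* from provenance.

## Worked example

```python
import htsupersage as ht

transcripts, ledger = ht.simulate_transcriptome(n_genes=50, length_range=(300, 800), seed=7)
weights = ht.simulate_expression(50, lognormal_sigma=1.0, seed=8)
specs = [
    ht.LibrarySpec("leaf", "GCCC", ht.NLAIII, n_reads=20_000, seed=1),
    ht.LibrarySpec("stem", "GCCA", ht.NLAIII, n_reads=20_000, seed=2),
]
reads, truth = ht.simulate_multiplexed_run(specs, transcripts, weights, seed=3)

table = ht.load_barcode_table([("leaf", "GCCC", "NlaIII"), ("stem", "GCCA", "NlaIII")])
profiles, stats = ht.demultiplex_fastq(reads, table)
print(f"classified {stats.classified}/{stats.total_reads} reads")
print("raw length 27 share:", round(stats.tag_length_histogram[27] / stats.classified, 3))
print("leaf:", ht.profile_summary(profiles["leaf"]))
leaf = ht.normalize_tpm(profiles["leaf"])
top = max(leaf.normalized, key=leaf.normalized.get)
print("most abundant leaf tag:", top, round(leaf.normalized[top], 1), "TPM")
print("leaf vs stem R2:", round(ht.pairwise_r2(profiles["leaf"], profiles["stem"]).r2, 4))
print("recovery exact:", profiles["leaf"].counts == truth.tag_counts("leaf"))
```

prints

```
classified 40000/40000 reads
raw length 27 share: 0.663
leaf: ProfileSummary(total_tags=20000, unique_tags=50, non_singleton_tags=50)
most abundant leaf tag: CATGCTCTACTGCCGTGCCTATTCCG 67350.0 TPM
leaf vs stem R2: 0.9971
recovery exact: True
```

Every read carries a valid index and anchoring site, so classification is
complete; the raw-tag-length mode sits at 27 as configured; both libraries
sample the same transcriptome, so their count profiles correlate with
R² ≈ 0.997; and with zero error rates the demultiplexed counts equal the
simulator's truth ledger tag-for-tag.

The same pipeline is available from the shell:

```bash
htsupersage simulate --config sim.yaml --out simdir --seed 11
htsupersage demux --fastq simdir/reads.fastq --barcodes barcodes.tsv --outdir out
htsupersage compare out/leaf.profile.tsv out/stem.profile.tsv
htsupersage census --fasta simdir/transcripts.fasta
```

(`summarize`, `normalize`, `filter`, `virtualtags`, `missing` and
`pipeline` subcommands round out the toolkit; see `htsupersage --help`.)

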