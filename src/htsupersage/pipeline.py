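"""End-to-end pipeline: demultiplex, summarize, normalize, compare.

Composes the library modules into one reproducible run that writes all its
artifacts to an output directory.  Runs are deterministic for a given input
and configuration; a header log line records the package version, a hash of
the configuration and the seed so runs can be matched to their outputs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .demux import ExtractionConfig, demultiplex_fastq, load_barcode_table, tag_length_histogram
from .profiles import normalize_tpm, pairwise_r2, profile_summary

log = logging.getLogger("htsupersage")

__all__ = ["RunConfig", "PipelineError", "pipeline_run"]


@dataclass
class RunConfig:
    fastq: str
    barcodes: str
    outdir: str
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    compare: bool = False
    compare_scale: str = "raw"
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(
            {**asdict(self), "version": __version__}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    """A stage failure; the message is prefixed with the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def pipeline_run(config: RunConfig) -> dict:
    """demux -> summarize -> normalize (-> compare); returns the report dict.

    Artifacts written under ``outdir``: per-sample profile TSVs (raw and
    normalized), extraction stats JSON, tag-length histogram TSV, summary
    TSV, optional pairwise R-squared TSV, and report.json aggregating
    everything.
    """
    from .io import write_profile, write_stats  # deferred to avoid cycle at import

    logging.basicConfig(level=config.log_level)
    log.info(
        "htsupersage %s | config=%s | seed=%d",
        __version__,
        config.config_hash(),
        config.seed,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        table = load_barcode_table(config.barcodes)
    except (OSError, ValueError, KeyError) as exc:
        raise PipelineError("barcodes", str(exc)) from exc

    try:
        profiles, stats = demultiplex_fastq(config.fastq, table, config.extraction)
    except (OSError, ValueError) as exc:
        raise PipelineError("demux", str(exc)) from exc
    for reason, n in sorted(stats.rejected_by_reason.items()):
        log.info("rejected %-15s %d", reason, n)

    report: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stats": stats.as_dict(),
        "samples": {},
    }

    try:
        write_stats(stats, outdir / "stats.json")
        if stats.classified:
            tag_length_histogram(stats).to_csv(
                outdir / "tag_length_histogram.tsv", sep="\t", index=False
            )
        for sample in sorted(profiles):
            profile = profiles[sample]
            total, unique, nonsingleton = profile_summary(profile)
            entry = {
                "total_tags": total,
                "unique_tags": unique,
                "non_singleton_tags": nonsingleton,
            }
            if total > 0:
                profile = normalize_tpm(profile)
                profiles[sample] = profile
            write_profile(profile, outdir / f"{sample}.profile.tsv")
            report["samples"][sample] = entry
    except (OSError, ValueError) as exc:
        raise PipelineError("profiles", str(exc)) from exc

    if config.compare:
        try:
            rows = []
            nonempty = [s for s in sorted(profiles) if profiles[s].counts]
            for a, b in itertools.combinations(nonempty, 2):
                res = pairwise_r2(profiles[a], profiles[b], scale=config.compare_scale)
                rows.append((a, b, res.r2, res.r))
            with open(outdir / "pairwise_r2.tsv", "w") as fh:
                fh.write("sample_a\tsample_b\tr2\tr\n")
                for a, b, r2, r in rows:
                    fh.write(f"{a}\t{b}\t{r2:.6f}\t{r:.6f}\n")
            report["pairwise_r2"] = [
                {"a": a, "b": b, "r2": r2, "r": r} for a, b, r2, r in rows
            ]
        except (OSError, ValueError) as exc:
            raise PipelineError("compare", str(exc)) from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
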