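"""End-to-end pipeline: demultiplex -> assign -> call -> quantify, with I/O.

Runs the whole analysis from raw FASTQ plus a sample sheet and panel
config, writing plain-TSV reports (with ``#``-prefixed provenance
header lines) and a JSON run manifest recording package version,
parameters and input checksums. Read counts are conserved across every
stage boundary: input = assigned + unassigned, and assigned =
called-pass + called-fail per reason; the run aborts if they are not.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from ampmeth.errors import AmpmethError, ConfigError
from ampmeth.calling import (
    MethylationCall,
    assign_amplicon,
    call_pattern,
    conversion_efficiency,
)
from ampmeth.demux import UNASSIGNED, SampleSheet, demultiplex, demux_report
from ampmeth.panel import PanelConfig, load_panel, reverse_complement
from ampmeth.quantify import (
    k_distribution,
    pattern_frequencies,
    replicate_summary,
    treg_like_fraction,
)

log = logging.getLogger("ampmeth")

CALL_COLUMNS = [
    "read_id",
    "sample_id",
    "replicate_id",
    "amplicon",
    "orientation",
    "pattern",
    "k_demethylated",
    "noncpg_c_total",
    "noncpg_c_unconverted",
    "identity_frac",
    "passed",
    "fail_reason",
]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; see the CLI for the flag surface."""

    fastq: tuple[str, ...]
    sample_sheet: str
    panel: str
    out_dir: str
    max_index_mismatch: int = 1
    max_primer_mismatch: int = 2
    min_identity: float = 0.90
    max_n: int = 0
    treg_min_k: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.fastq, (str, os.PathLike)):
            self.fastq = (str(self.fastq),)
        self.fastq = tuple(str(p) for p in self.fastq)
        if not (0.0 <= self.min_identity <= 1.0):
            raise ConfigError(f"min_identity {self.min_identity} outside [0, 1]")
        if self.max_index_mismatch < 0 or self.max_primer_mismatch < 0 or self.max_n < 0:
            raise ConfigError("mismatch/N thresholds must be non-negative")
        for path in (*self.fastq, self.sample_sheet, self.panel):
            if not os.path.exists(path):
                raise ConfigError(f"input path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, Mapping):
            raise ConfigError(f"run config {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown run-config key(s): {sorted(unknown)}")
        return cls(**doc)


@dataclass
class PipelineResult:
    exit_code: int
    counts: dict
    out_dir: str
    outputs: dict


def _open_text(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(paths: Sequence[str]) -> Iterator[tuple[str, str, str]]:
    """Stream ``(read_id, seq, qual)`` from one or more FASTQ files (gzip ok)."""
    for path in paths:
        with _open_text(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
                yield rec.id, str(rec.seq).upper(), qual


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, provenance: Mapping) -> None:
    with open(path, "w") as fh:
        for key in sorted(provenance):
            fh.write(f"# {key}={provenance[key]}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def call_reads(
    reads: Iterable[tuple],
    sheet: SampleSheet,
    panel: PanelConfig,
    max_index_mismatch: int = 1,
    max_primer_mismatch: int = 2,
    min_identity: float = 0.90,
    max_n: int = 0,
) -> tuple[list[MethylationCall], Counter, Counter]:
    """Demultiplex, amplicon-assign and pattern-call a read stream.

    Returns ``(calls, demux_counts, amplicon_counts)`` where
    ``amplicon_counts`` tracks per-read amplicon assignment outcomes
    (including ``UNMATCHED``).
    """
    calls: list[MethylationCall] = []
    demux_counts: Counter = Counter()
    amp_counts: Counter = Counter()
    for entry, read_id, seq, _qual in demultiplex(
        reads, sheet, max_mismatch=max_index_mismatch
    ):
        if entry is None:
            demux_counts[UNASSIGNED] += 1
            continue
        demux_counts[entry.key] += 1
        hit = assign_amplicon(seq, panel, max_primer_mismatch=max_primer_mismatch)
        if hit is None:
            amp_counts["UNMATCHED"] += 1
            continue
        amp, orientation = hit
        amp_counts[amp.name] += 1
        oriented = seq if orientation == "+" else reverse_complement(seq)
        trimmed = oriented[len(amp.forward_primer) :]
        calls.append(
            call_pattern(
                trimmed,
                amp,
                read_id=read_id,
                min_identity=min_identity,
                max_n=max_n,
                sample_id=entry.sample_id,
                replicate_id=entry.replicate_id,
                orientation=orientation,
            )
        )
    return calls, demux_counts, amp_counts


def calls_to_frame(calls: Sequence[MethylationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "sample_id": c.sample_id,
                "replicate_id": c.replicate_id,
                "amplicon": c.amplicon,
                "orientation": c.orientation,
                "pattern": c.pattern,
                "k_demethylated": c.k_demethylated,
                "noncpg_c_total": c.noncpg_c_total,
                "noncpg_c_unconverted": c.noncpg_c_unconverted,
                "identity_frac": c.identity_frac,
                "passed": c.passed,
                "fail_reason": c.fail_reason,
            }
            for c in calls
        ],
        columns=CALL_COLUMNS,
    )


def calls_from_frame(df: pd.DataFrame) -> list[MethylationCall]:
    """Rehydrate calls from a calls TSV previously written by the pipeline."""
    df = df.fillna({"pattern": "", "fail_reason": "", "sample_id": "", "replicate_id": ""})
    return [
        MethylationCall(
            read_id=str(r.read_id),
            amplicon=str(r.amplicon),
            pattern=str(r.pattern) if str(r.pattern) != "nan" else "",
            k_demethylated=int(r.k_demethylated),
            noncpg_c_total=int(r.noncpg_c_total),
            noncpg_c_unconverted=int(r.noncpg_c_unconverted),
            identity_frac=float(r.identity_frac),
            passed=bool(r.passed),
            fail_reason=str(r.fail_reason),
            sample_id=str(r.sample_id),
            replicate_id=str(r.replicate_id),
            orientation=str(r.orientation),
        )
        for r in df.itertuples()
    ]


def quantify_calls(
    calls: Sequence[MethylationCall],
    panel: PanelConfig,
    treg_min_k: Mapping[str, int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Aggregate calls into the pipeline's report tables.

    ``treg_min_k`` maps amplicon name to the Treg-like threshold; the
    default per amplicon is ``n_included - 1`` (the 8-or-9-of-9
    convention); set an amplicon to ``n_included`` to require complete
    demethylation.
    """
    treg_min_k = dict(treg_min_k or {})
    df = calls_to_frame(calls)
    pattern_rows, kdist_rows, summary_rows, qc_rows = [], [], [], []
    treg_values: dict[tuple[str, str], list[tuple[str, float]]] = {}

    group_cols = ["sample_id", "amplicon", "replicate_id"]
    if not df.empty:
        for (sample, amp_name, rep), sub in df.groupby(group_cols, sort=True):
            sub_calls = [calls[i] for i in sub.index]
            amp = panel[amp_name]
            n = amp.n_included
            min_k = treg_min_k.get(amp_name, n - 1)

            freqs = pattern_frequencies(sub_calls) if any(
                c.passed and "N" not in c.pattern for c in sub_calls
            ) else pd.DataFrame(columns=["pattern", "count", "frequency"])
            for r in freqs.itertuples():
                pattern_rows.append(
                    dict(sample_id=sample, amplicon=amp_name, replicate_id=rep,
                         pattern=r.pattern, count=r.count, frequency=r.frequency)
                )
            eligible = not freqs.empty
            if eligible:
                kvec = k_distribution(sub_calls, n_sites=n)
                for k, frac in enumerate(kvec):
                    kdist_rows.append(
                        dict(sample_id=sample, amplicon=amp_name, replicate_id=rep,
                             k=k, fraction=frac)
                    )
                treg = treg_like_fraction(sub_calls, min_k=min_k)
                treg_values.setdefault((sample, amp_name), []).append((rep, treg))

            qc = conversion_efficiency(sub_calls, amplicon=amp_name, sample=sample) if any(
                c.passed for c in sub_calls
            ) else None
            qc_rows.append(
                dict(
                    sample_id=sample,
                    amplicon=amp_name,
                    replicate_id=rep,
                    reads_in=len(sub_calls),
                    passed=int(sum(c.passed for c in sub_calls)),
                    failed_low_identity=int(sum(c.fail_reason == "LOW_IDENTITY" for c in sub_calls)),
                    failed_too_many_n=int(sum(c.fail_reason == "TOO_MANY_N" for c in sub_calls)),
                    failed_too_short=int(sum(c.fail_reason == "TOO_SHORT" for c in sub_calls)),
                    noncpg_c_observations=qc.observations if qc else 0,
                    conversion_efficiency_pct=(
                        qc.efficiency if qc and qc.efficiency is not None else float("nan")
                    ),
                )
            )

    for (sample, amp_name), values in sorted(treg_values.items()):
        amp = panel[amp_name]
        min_k = treg_min_k.get(amp_name, amp.n_included - 1)
        summ = replicate_summary(
            f"treg_like_pct_min_k_{min_k}", [v for _, v in values]
        )
        summary_rows.append(
            dict(
                sample_id=sample,
                amplicon=amp_name,
                statistic=summ.statistic,
                median=summ.median,
                min=summ.minimum,
                max=summ.maximum,
                n_replicates=summ.n_replicates,
            )
        )

    return {
        "calls": df,
        "pattern_table": pd.DataFrame(
            pattern_rows,
            columns=["sample_id", "amplicon", "replicate_id", "pattern", "count", "frequency"],
        ),
        "k_distribution": pd.DataFrame(
            kdist_rows, columns=["sample_id", "amplicon", "replicate_id", "k", "fraction"]
        ),
        "summary": pd.DataFrame(
            summary_rows,
            columns=["sample_id", "amplicon", "statistic", "median", "max", "min", "n_replicates"],
        ),
        "qc_report": pd.DataFrame(
            qc_rows,
            columns=[
                "sample_id", "amplicon", "replicate_id", "reads_in", "passed",
                "failed_low_identity", "failed_too_many_n", "failed_too_short",
                "noncpg_c_observations", "conversion_efficiency_pct",
            ],
        ),
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute demultiplex -> assign -> call -> quantify and write reports.

    Deterministic: re-running with the same inputs and config produces
    byte-identical reports.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = load_panel(config.panel)
    sheet = SampleSheet.from_table(config.sample_sheet)
    log.info("panel: %d amplicon(s); sheet: %d assignment(s)", len(panel), len(sheet.assignments))

    total_reads = 0

    def _counted():
        nonlocal total_reads
        for item in iter_fastq(config.fastq):
            total_reads += 1
            yield item

    calls, demux_counts, amp_counts = call_reads(
        _counted(),
        sheet,
        panel,
        max_index_mismatch=config.max_index_mismatch,
        max_primer_mismatch=config.max_primer_mismatch,
        min_identity=config.min_identity,
        max_n=config.max_n,
    )

    assigned = sum(v for k, v in demux_counts.items() if k != UNASSIGNED)
    unassigned = demux_counts.get(UNASSIGNED, 0)
    if assigned + unassigned != total_reads:
        raise AmpmethError("read-count conservation violated at demultiplexing")
    if sum(amp_counts.values()) != assigned:
        raise AmpmethError("read-count conservation violated at amplicon assignment")
    if len(calls) != assigned - amp_counts.get("UNMATCHED", 0):
        raise AmpmethError("read-count conservation violated at calling")
    if total_reads == 0 or assigned == 0:
        log.warning("no reads passed demultiplexing; reports will be empty")

    tables = quantify_calls(calls, panel, treg_min_k=config.treg_min_k)

    provenance = {
        "max_index_mismatch": config.max_index_mismatch,
        "max_primer_mismatch": config.max_primer_mismatch,
        "min_identity": config.min_identity,
        "max_n": config.max_n,
        "panel": os.path.basename(config.panel),
        "seed": config.seed,
    }
    outputs = {}
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        _write_tsv(df, path, provenance)
        outputs[name] = str(path)
    demux_path = out / "demux_report.tsv"
    _write_tsv(demux_report(demux_counts), demux_path, provenance)
    outputs["demux_report"] = str(demux_path)

    from ampmeth import __version__

    counts = {
        "total_reads": total_reads,
        "assigned": assigned,
        "unassigned": unassigned,
        "amplicon_unmatched": amp_counts.get("UNMATCHED", 0),
        "called": len(calls),
        "called_passed": int(sum(c.passed for c in calls)),
    }
    manifest = {
        "ampmeth_version": __version__,
        "parameters": {**provenance, "treg_min_k": dict(config.treg_min_k)},
        "inputs": {
            os.path.basename(p): _sha256(p)
            for p in (*config.fastq, config.sample_sheet, config.panel)
        },
        "counts": counts,
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["manifest"] = str(manifest_path)

    log.info("run complete: %s", counts)
    return PipelineResult(exit_code=0, counts=counts, out_dir=str(out), outputs=outputs)
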