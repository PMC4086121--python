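"""End-to-end prediction run: validate -> filter -> extract -> score -> rank.

Mirrors the results-page flow of an online precursor screen: ambiguous
records are removed and counted, an optional signal-peptide filter drops
sequences that are not plausibly secreted, survivors are scored by all
four models, and records are ranked by Internal Score with a
high-quality subset above a configurable IS threshold.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import feature_extraction, motif_scan, sequence_io
from .classifier import MODEL_NAMES, ModelBundle, call_positive
from .sequence_io import ProteinSequence

DEFAULT_HQ_THRESHOLD = 2.0  # percent IS; package default, reported in output

# signal-peptide heuristic parameters (NOT equivalent to SignalP: no
# cleavage-site model, no evolutionary information — a hydrophobic-core
# screen only)
SP_WINDOW = 7
SP_REGION = 25
SP_MIN_HYDROPATHY = 1.0


@dataclass(frozen=True)
class PredictionRecord:
    """Scored result for one sequence."""

    id: str
    probs: dict[str, float]
    calls: dict[str, bool]
    overall_call: bool
    internal_score: float
    sp_call: bool | None
    high_quality: bool
    below_sp_length: bool = False

    @property
    def n_models_agreeing(self) -> int:
        return sum(self.calls.values())

    @property
    def max_prob(self) -> float:
        return max(self.probs.values())

    def as_dict(self) -> dict:
        row = {"id": self.id}
        for name in MODEL_NAMES:
            row[f"prob_{name}"] = self.probs[name]
        for name in MODEL_NAMES:
            row[f"call_{name}"] = self.calls[name]
        row["overall_call"] = self.overall_call
        row["n_models_agreeing"] = self.n_models_agreeing
        row["internal_score"] = self.internal_score
        row["sp_call"] = "unknown" if self.sp_call is None else self.sp_call
        row["high_quality"] = self.high_quality
        return row


@dataclass
class RunSummary:
    """Partition of an input set; the counts always sum to n_input."""

    n_input: int
    n_removed_invalid: int
    n_sp_filtered: int
    n_positive: int
    n_negative: int
    agreement_histogram: dict[int, int]
    hq_threshold: float
    n_high_quality: int
    removed: list[tuple[str, str]] = field(default_factory=list)


def sp_heuristic(seq: ProteinSequence) -> bool:
    """Built-in secreted-protein screen: hydrophobic core near the N-terminus.

    True iff some window of 7 consecutive residues, starting at position 2
    or later (after the initiator Met) and lying entirely within the first
    25 residues, has mean Kyte–Doolittle hydropathy >= 1.0.  Sequences
    shorter than 8 residues can never pass.  This fallback is NOT
    equivalent to SignalP.
    """
    region = seq.residues[:SP_REGION]
    if len(region) < SP_WINDOW + 1:
        return False
    kd = np.array([feature_extraction.KD[c] for c in region])
    sums = np.convolve(kd, np.ones(SP_WINDOW), mode="valid")
    # index 0 of sums = window starting at residue 1; require start >= 2
    return bool(np.any(sums[1:] / SP_WINDOW >= SP_MIN_HYDROPATHY))


def external_sp_adapter(
    command_template: str,
    sequences: Sequence[ProteinSequence],
) -> dict[str, bool]:
    """Run an external signal-peptide predictor and parse per-id flags.

    ``command_template`` must contain ``{fasta}``, replaced by a temporary
    FASTA path.  Expected short-format output: one line per sequence,
    ``<id><whitespace><Y|N>`` (lines starting with ``#`` ignored).  Any
    missing id, nonzero exit or unparseable output raises with the
    captured output attached.
    """
    exe = command_template.split()[0]
    if shutil.which(exe) is None and not Path(exe).exists():
        raise FileNotFoundError(f"external SP command not found: {exe!r}")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "input.fasta"
        sequence_io.write_fasta(sequences, fasta)
        cmd = command_template.format(fasta=fasta)
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"external SP command failed (exit {proc.returncode}):\n"
                f"{proc.stderr or proc.stdout}"
            )
    flags: dict[str, bool] = {}
    for line in proc.stdout.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2 or fields[1].upper() not in ("Y", "N"):
            raise ValueError(f"unparseable SP output line: {line!r}")
        flags[fields[0]] = fields[1].upper() == "Y"
    missing = [s.id for s in sequences if s.id not in flags]
    if missing:
        raise ValueError(f"SP output missing ids: {missing}")
    return flags


def agreement_partition(records: Iterable[PredictionRecord]) -> dict[int, int]:
    """Counts of records by number of models calling positive (0..4)."""
    hist = {k: 0 for k in range(5)}
    for rec in records:
        hist[rec.n_models_agreeing] += 1
    return hist


def run(
    records: str | Path | Sequence[ProteinSequence],
    bundle: ModelBundle,
    sp_filter: str = "off",
    sp_command: str | None = None,
    hq_threshold: float = DEFAULT_HQ_THRESHOLD,
    score_filtered: bool = False,
) -> tuple[RunSummary, list[PredictionRecord]]:
    """Score a FASTA file (or records) end to end.

    ``sp_filter``: ``"off"``, ``"heuristic"`` (built-in hydrophobic-core
    screen) or ``"external"`` (requires ``sp_command``, a template with
    ``{fasta}``).  Filtered-out sequences are excluded from scoring and
    counted, unless ``score_filtered`` is set, in which case they are
    scored with their ``sp_call`` recorded.

    Records are sorted by Internal Score descending, ties broken by the
    maximum model probability then input order.  ``high_quality`` means a
    positive overall call with IS >= ``hq_threshold``.
    """
    if isinstance(records, (str, Path)):
        records = sequence_io.read_fasta(records)
    records = list(records)
    valid, removed = sequence_io.partition_valid(records)

    sp_flags: dict[int, bool | None]
    if sp_filter == "off":
        sp_flags = {i: None for i in range(len(valid))}
    elif sp_filter == "heuristic":
        sp_flags = {i: sp_heuristic(s) for i, s in enumerate(valid)}
    elif sp_filter == "external":
        if not sp_command:
            raise ValueError("sp_filter='external' requires sp_command")
        by_id = external_sp_adapter(sp_command, valid)
        sp_flags = {i: by_id[s.id] for i, s in enumerate(valid)}
    else:
        raise ValueError(f"unknown sp_filter {sp_filter!r}")

    if sp_filter == "off" or score_filtered:
        survivors = list(enumerate(valid))
        n_sp_filtered = 0
    else:
        survivors = [(i, s) for i, s in enumerate(valid) if sp_flags[i]]
        n_sp_filtered = len(valid) - len(survivors)

    results: list[PredictionRecord] = []
    if survivors:
        seqs = [s for _, s in survivors]
        X = feature_extraction.extract_matrix(seqs)
        probs = bundle.predict_matrix(X)
        for row, (i, seq) in enumerate(survivors):
            p = {name: float(probs[name].iloc[row]) for name in MODEL_NAMES}
            calls, overall = call_positive(p, bundle.thresholds)
            ann = motif_scan.annotate(seq)
            hq = overall and ann.internal_score >= hq_threshold
            results.append(PredictionRecord(
                id=seq.id, probs=p, calls=calls, overall_call=overall,
                internal_score=ann.internal_score, sp_call=sp_flags[i],
                high_quality=hq,
                below_sp_length=seq.length <= motif_scan.DEFAULT_SP_TRIM,
            ))

    order = sorted(
        range(len(results)),
        key=lambda j: (-results[j].internal_score, -results[j].max_prob, j),
    )
    results = [results[j] for j in order]

    n_positive = sum(r.overall_call for r in results)
    summary = RunSummary(
        n_input=len(records),
        n_removed_invalid=len(removed),
        n_sp_filtered=n_sp_filtered,
        n_positive=n_positive,
        n_negative=len(results) - n_positive,
        agreement_histogram=agreement_partition(results),
        hq_threshold=hq_threshold,
        n_high_quality=sum(r.high_quality for r in results),
        removed=[(rec.id, reason) for rec, reason in removed],
    )
    return summary, results


def write_run_outputs(
    summary: RunSummary,
    results: list[PredictionRecord],
    sequences_by_id: dict[str, ProteinSequence],
    out_dir: str | Path,
) -> None:
    """Write the result-set files: summary, detailed and HQ tables, and a
    FASTA of positive predictions for forwarding to downstream tools."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sequence_io.write_results(results, out / "detailed.tsv", "tsv")
    hq = [r for r in results if r.high_quality]
    sequence_io.write_results(hq, out / "high_quality.tsv", "tsv")
    with open(out / "summary.tsv", "w") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"n_input\t{summary.n_input}\n")
        fh.write(f"n_removed_invalid\t{summary.n_removed_invalid}\n")
        fh.write(f"n_sp_filtered\t{summary.n_sp_filtered}\n")
        fh.write(f"n_positive\t{summary.n_positive}\n")
        fh.write(f"n_negative\t{summary.n_negative}\n")
        fh.write(f"hq_threshold\t{summary.hq_threshold}\n")
        fh.write(f"n_high_quality\t{summary.n_high_quality}\n")
        for k in range(5):
            fh.write(f"agreement_{k}\t{summary.agreement_histogram[k]}\n")
    positives = [sequences_by_id[r.id] for r in results
                 if r.overall_call and r.id in sequences_by_id]
    sequence_io.write_fasta(positives, out / "positive.fasta")
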