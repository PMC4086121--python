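"""Synthetic labeled sequence sets with neuropeptide-precursor architecture.

A real precursor is a secreted protein: an N-terminal hydrophobic
signal-peptide-like segment (~25 aa), followed by several short mature
peptide units (most are 5–30 aa) each flanked by a dibasic (KK/KR/RK/RR)
or tribasic cleavage motif, and a short tail.  The positive generator
emits exactly this architecture and records every planted flank as
ground truth.  Negatives are background-composition sequences in three
flavours: ``uniform-background`` (each residue 1/20), ``globular-like``
(average protein composition) and ``nuclear-like`` (Lys/Arg-enriched
overall but with clustered basic runs suppressed by rejection sampling —
basic-rich yet poor in cleavage motifs, the hard negative class).

Determinism: the same config and seed reproduce identical records byte
for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .sequence_io import CANONICAL_AA, ProteinSequence

# Average residue frequencies of well-characterised proteins (Swiss-Prot
# style background), hard-coded so nothing is downloaded.  Percent units;
# normalised at use.
GLOBULAR_COMPOSITION = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.37,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}

DIBASIC_FLANKS = ("KK", "KR", "RK", "RR")
TRIBASIC_FLANKS = ("KKR", "KRR", "RKR")

_REJECTION_CAP = 10_000


def _background_probs(table: dict[str, float]) -> np.ndarray:
    p = np.array([table[a] for a in CANONICAL_AA], dtype=float)
    return p / p.sum()


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one generated set.

    ``flank_weights`` is the sampling distribution over flank motifs for
    positives; ``negative_class`` selects the background flavour for
    negatives.  ``sanitized`` removes spontaneous basic residues from the
    non-flank parts of positives so planted motifs are the only ones
    (oracle mode for ground-truth tests).
    """

    n_sequences: int = 100
    seed: int = 0
    length_range: tuple[int, int] = (100, 400)  # negatives, aa
    sp_length: int = 25
    n_repeats_range: tuple[int, int] = (3, 8)
    repeat_length_range: tuple[int, int] = (5, 30)
    flank_weights: dict[str, float] = field(default_factory=lambda: {
        "KK": 0.30, "KR": 0.30, "RK": 0.15, "RR": 0.15, "tribasic": 0.10,
    })
    background: dict[str, float] = field(
        default_factory=lambda: dict(GLOBULAR_COMPOSITION))
    negative_class: str = "globular-like"
    sanitized: bool = False

    def validated(self) -> "GeneratorConfig":
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be >= 0")
        for lo, hi in (self.length_range, self.n_repeats_range,
                       self.repeat_length_range):
            if lo > hi or lo < 0:
                raise ValueError(f"empty or negative range ({lo}, {hi})")
        w = sum(self.flank_weights.values())
        if w <= 0:
            raise ValueError("flank weights must have positive mass")
        if self.negative_class not in (
                "uniform-background", "nuclear-like", "globular-like"):
            raise ValueError(f"unknown negative_class {self.negative_class!r}")
        return self


def _sample_background(rng: np.random.Generator, n: int,
                       probs: np.ndarray, no_basic: bool = False) -> str:
    if n <= 0:
        return ""
    if no_basic:
        probs = probs.copy()
        for aa in "KR":
            probs[CANONICAL_AA.index(aa)] = 0.0
        probs = probs / probs.sum()
    idx = rng.choice(20, size=n, p=probs)
    return "".join(CANONICAL_AA[i] for i in idx)


def _protect_ends(segment: str, rng: np.random.Generator) -> str:
    """Force segment boundary residues non-basic so planted flanks stay
    maximal runs of exactly their own length."""
    safe = "ASTGQNPL"
    chars = list(segment)
    for pos in (0, -1):
        if chars and chars[pos] in "KR":
            chars[pos] = safe[rng.integers(len(safe))]
    return "".join(chars)


def _signal_peptide(rng: np.random.Generator, sp_length: int) -> str:
    """M + short charged stretch + hydrophobic core + polar fill."""
    core_len = max(sp_length - 6, 7)
    n_basic = int(rng.integers(1, 3))
    head = "M" + "".join(rng.choice(list("KR"), size=n_basic))
    core = "".join(rng.choice(list("LAVIF"), size=core_len,
                              p=[0.35, 0.25, 0.2, 0.1, 0.1]))
    fill_len = max(sp_length - len(head) - core_len, 0)
    fill = "".join(rng.choice(list("ASTG"), size=fill_len))
    return (head + core + fill)[:sp_length]


def generate_positive(
    config: GeneratorConfig,
) -> tuple[list[ProteinSequence], list[tuple[str, int, int, str]]]:
    """Emit precursor-architecture sequences and their planted flank map.

    Returns (records, ground_truth) where ground truth rows are
    ``(seq_id, start, end, motif_class)`` with 1-based inclusive
    coordinates of every planted di/tribasic flank.
    """
    config = config.validated()
    rng = np.random.default_rng(config.seed)
    probs = _background_probs(config.background)
    flank_names = sorted(config.flank_weights)
    flank_p = np.array([config.flank_weights[k] for k in flank_names])
    flank_p = flank_p / flank_p.sum()

    records, truth = [], []
    for i in range(config.n_sequences):
        seq_id = f"pos_{config.seed}_{i:04d}"
        parts = [_signal_peptide(rng, config.sp_length)]
        spacer = _sample_background(rng, int(rng.integers(3, 11)), probs,
                                    no_basic=config.sanitized)
        parts.append(_protect_ends(spacer, rng))
        planted = []
        n_rep = int(rng.integers(config.n_repeats_range[0],
                                 config.n_repeats_range[1] + 1))
        pos_cursor = sum(len(p) for p in parts)
        for _ in range(n_rep):
            ulen = int(rng.integers(config.repeat_length_range[0],
                                    config.repeat_length_range[1] + 1))
            unit = _sample_background(rng, ulen, probs,
                                      no_basic=config.sanitized)
            unit = _protect_ends(unit, rng)
            choice = flank_names[rng.choice(len(flank_names), p=flank_p)]
            if choice == "tribasic":
                motif = TRIBASIC_FLANKS[rng.integers(len(TRIBASIC_FLANKS))]
                cls = "tribasic"
            else:
                motif = choice
                cls = "dibasic"
            start = pos_cursor + len(unit) + 1  # 1-based
            planted.append((seq_id, start, start + len(motif) - 1, cls))
            parts.append(unit + motif)
            pos_cursor += len(unit) + len(motif)
        tail = _sample_background(rng, int(rng.integers(5, 21)), probs,
                                  no_basic=config.sanitized)
        parts.append(_protect_ends(tail, rng))
        residues = "".join(parts)
        records.append(ProteinSequence(
            id=seq_id,
            description=f"synthetic precursor n_repeats={n_rep}",
            residues=residues,
        ))
        truth.extend(planted)
    return records, truth


def generate_negative(config: GeneratorConfig) -> list[ProteinSequence]:
    """Background-composition sequences without precursor architecture."""
    config = config.validated()
    rng = np.random.default_rng(config.seed)
    if config.negative_class == "uniform-background":
        probs = np.full(20, 0.05)
    elif config.negative_class == "globular-like":
        probs = _background_probs(config.background)
    else:  # nuclear-like: K/R enriched, runs >= 2 rejected
        table = dict(config.background)
        table["K"] *= 2.0
        table["R"] *= 2.0
        probs = _background_probs(table)

    records = []
    tag = config.negative_class.split("-")[0]
    for i in range(config.n_sequences):
        n = int(rng.integers(config.length_range[0],
                             config.length_range[1] + 1))
        if config.negative_class == "nuclear-like":
            chars: list[str] = []
            for _ in range(n):
                for attempt in range(_REJECTION_CAP + 1):
                    c = CANONICAL_AA[rng.choice(20, p=probs)]
                    if not (chars and c in "KR" and chars[-1] in "KR"):
                        break
                else:
                    raise RuntimeError("rejection-sampling retry cap exceeded")
                chars.append(c)
            residues = "".join(chars)
        else:
            residues = _sample_background(rng, n, probs)
        records.append(ProteinSequence(
            id=f"neg_{tag}_{config.seed}_{i:04d}",
            description=f"synthetic negative ({config.negative_class})",
            residues=residues,
        ))
    return records


def training_sets(
    n_pos: int, n_neg: int, seed: int,
    config: GeneratorConfig | None = None,
) -> tuple[list[ProteinSequence], list[ProteinSequence]]:
    """Default study sets: positives vs a pooled negative set.

    Negatives pool two independent flavours half-and-half (nuclear-like
    and globular-like), mirroring training against several negative sets.
    """
    base = (config or GeneratorConfig()).validated()
    pos, _ = generate_positive(replace(base, n_sequences=n_pos, seed=seed))
    n_half = n_neg // 2
    neg_a = generate_negative(replace(
        base, n_sequences=n_half, seed=seed + 1,
        negative_class="nuclear-like"))
    neg_b = generate_negative(replace(
        base, n_sequences=n_neg - n_half, seed=seed + 2,
        negative_class="globular-like"))
    return pos, neg_a + neg_b


def write_ground_truth(truth: list[tuple[str, int, int, str]],
                       path: str | Path) -> None:
    """BED-like TSV of planted flank motifs (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("id\tstart\tend\tmotif_class\n")
        for seq_id, start, end, cls in truth:
            fh.write(f"{seq_id}\t{start}\t{end}\t{cls}\n")
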