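"""Fixed 560-dimensional sequence descriptor vector.

Every validated sequence is converted into the same ordered vector of
560 named features in three groups:

* **composition** (20) — frequency of each canonical residue,
  alphabetical order; sums to 1.
* **bigram** (400) — overlapping ordered residue-pair frequencies over
  the 20x20 alphabet, lexicographic order, normalised by L-1 so the
  group sums to 1 for L >= 2 (all zeros for L = 1).  Normalisation
  removes the length confound; length is its own feature below.
* **physchem** (140) — a versioned catalog of biophysical and
  informational-statistical descriptors (see :data:`PHYSCHEM_NAMES`):
  global scalars (length, molecular weight, isoelectric point, GRAVY
  hydropathy, instability index, aromaticity, net charge at pH 7,
  reduced molar extinction, Shannon entropy of composition, maximal
  basic and hydrophobic run lengths, secondary-structure fractions),
  Kyte–Doolittle hydropathy-profile statistics, residue-class
  fractions, basic-site/motif counts and per-100-residue densities
  (full-length and post-signal-peptide-trim variants) including the
  Internal Score, N- and C-terminal 25-residue window compositions and
  scalars, and 49 reduced-alphabet (7-class) bigram frequencies.

The catalog is frozen under :data:`CATALOG_VERSION`; trained models
record the version and refuse vectors built under a different one, so
train/predict feature order can never silently drift.

Degenerate inputs are handled, not rejected: bigram groups are all-zero
for single-residue sequences, and terminal windows shorter than 25
residues use the available prefix/suffix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import ProtParamData
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from . import motif_scan
from .sequence_io import CANONICAL_AA, ProteinSequence

CATALOG_VERSION = "npid-560-v1"

KD = ProtParamData.kd  # Kyte–Doolittle hydropathy scale

# Residue classes used for the fraction features (Taylor-style groupings).
CLASS_SETS = {
    "charged": set("DEKRH"),
    "polar": set("NQSTYCH"),
    "hydrophobic": set("AILMFWV"),
    "aromatic": set("FWY"),
    "tiny": set("AGCS"),
    "small": set("ACDGNPSTV"),
    "basic": set("KRH"),
    "acidic": set("DE"),
}

# Seven-class reduced alphabet partitioning all 20 residues, used for the
# class-bigram features: s small, h aliphatic-hydrophobic, r aromatic,
# b basic, a acidic, p polar-amide, x proline.
REDUCED_CLASSES = (
    ("s", "AGST"),
    ("h", "ILMV"),
    ("r", "FWY"),
    ("b", "KRH"),
    ("a", "DE"),
    ("p", "NQC"),
    ("x", "P"),
)
_REDUCED_OF = {aa: i for i, (_, members) in enumerate(REDUCED_CLASSES)
               for aa in members}

TERMINAL_WINDOW = 25  # aa; matches the typical signal-peptide length
HYD_PROFILE_WINDOW = 9  # aa; sliding window for the hydropathy profile

COMPOSITION_NAMES = tuple(f"comp_{a}" for a in CANONICAL_AA)
BIGRAM_NAMES = tuple(f"bg_{a}{b}" for a in CANONICAL_AA for b in CANONICAL_AA)

_GLOBAL_NAMES = (
    "length", "molecular_weight", "isoelectric_point", "gravy",
    "instability_index", "aromaticity", "net_charge_ph7",
    "extinction_coeff_reduced", "shannon_entropy",
    "max_run_basic", "max_run_hydrophobic",
    "helix_fraction", "turn_fraction", "sheet_fraction",
)
_PROFILE_NAMES = (
    "hyd_profile_mean", "hyd_profile_var", "hyd_profile_min",
    "hyd_profile_max", "hyd_profile_q25", "hyd_profile_median",
    "hyd_profile_q75",
)
_FRACTION_NAMES = tuple(f"frac_{k}" for k in CLASS_SETS)
_MOTIF_NAMES = (
    "count_K", "count_R", "dens_K", "dens_R",
    "n_single_basic", "n_dibasic", "n_tribasic",
    "dens_single_basic", "dens_dibasic", "dens_tribasic",
    "dens_single_basic_trim", "dens_dibasic_trim", "dens_tribasic_trim",
    "internal_score", "mean_motif_spacing", "n_motifs_nterm25",
)
_NTERM_NAMES = tuple(f"nterm25_{a}" for a in CANONICAL_AA)
_CTERM_NAMES = tuple(f"cterm25_{a}" for a in CANONICAL_AA)
_TERM_SCALAR_NAMES = (
    "nterm25_gravy", "nterm25_net_charge", "nterm25_max_hydrophobic_run",
    "cterm25_gravy", "cterm25_net_charge", "cterm25_basic_fraction",
)
_CLASS_BIGRAM_NAMES = tuple(
    f"cbg_{c1}{c2}" for c1, _ in REDUCED_CLASSES for c2, _ in REDUCED_CLASSES
)

PHYSCHEM_NAMES = (
    _GLOBAL_NAMES + _PROFILE_NAMES + _FRACTION_NAMES + _MOTIF_NAMES
    + _NTERM_NAMES + _CTERM_NAMES + _TERM_SCALAR_NAMES + _CLASS_BIGRAM_NAMES
)
assert len(PHYSCHEM_NAMES) == 140

FEATURE_NAMES: tuple[str, ...] = COMPOSITION_NAMES + BIGRAM_NAMES + PHYSCHEM_NAMES
assert len(FEATURE_NAMES) == 560

_AA_INDEX = {a: i for i, a in enumerate(CANONICAL_AA)}


@dataclass(frozen=True)
class FeatureVector:
    """Ordered, named 560-feature descriptor of one sequence."""

    values: np.ndarray
    catalog_version: str = CATALOG_VERSION

    names = FEATURE_NAMES

    def __post_init__(self):
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ValueError(
                f"feature vector must have length {len(FEATURE_NAMES)}, "
                f"got {self.values.shape}"
            )

    @property
    def composition(self) -> np.ndarray:
        return self.values[:20]

    @property
    def bigram(self) -> np.ndarray:
        return self.values[20:420]

    @property
    def physchem(self) -> np.ndarray:
        return self.values[420:]


def aa_composition(seq: ProteinSequence) -> np.ndarray:
    """Per-residue frequency (count / length), alphabetical order."""
    idx = np.fromiter((_AA_INDEX[c] for c in seq.residues), dtype=np.intp,
                      count=seq.length)
    counts = np.bincount(idx, minlength=20).astype(float)
    return counts / seq.length


def bigram_frequencies(seq: ProteinSequence) -> np.ndarray:
    """Overlapping ordered-pair frequencies over the 400 pairs.

    Normalised by L-1; all zeros when L < 2.
    """
    out = np.zeros(400)
    if seq.length < 2:
        return out
    idx = np.fromiter((_AA_INDEX[c] for c in seq.residues), dtype=np.intp,
                      count=seq.length)
    pair = idx[:-1] * 20 + idx[1:]
    counts = np.bincount(pair, minlength=400).astype(float)
    return counts / (seq.length - 1)


def _max_run(residues: str, members: set[str] | frozenset[str]) -> int:
    best = cur = 0
    for c in residues:
        cur = cur + 1 if c in members else 0
        best = max(best, cur)
    return best


def _window_stats(residues: str) -> tuple[np.ndarray, float, float, int]:
    """(composition, gravy, net charge at pH 7, max hydrophobic run)."""
    comp = np.zeros(20)
    for c in residues:
        comp[_AA_INDEX[c]] += 1
    comp /= max(len(residues), 1)
    gravy = float(np.mean([KD[c] for c in residues])) if residues else 0.0
    charge = float(ProteinAnalysis(residues).charge_at_pH(7.0)) if residues else 0.0
    run = _max_run(residues, CLASS_SETS["hydrophobic"])
    return comp, gravy, charge, run


def physchem_features(seq: ProteinSequence) -> np.ndarray:
    """The 140 physicochemical/statistical descriptors, catalog order."""
    s = seq.residues
    L = seq.length
    pa = ProteinAnalysis(s)
    comp = aa_composition(seq)

    helix, turn, sheet = pa.secondary_structure_fraction()
    nz = comp[comp > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    global_vals = [
        float(L),
        pa.molecular_weight(),
        pa.isoelectric_point(),
        pa.gravy(),
        pa.instability_index() if L >= 2 else 0.0,
        pa.aromaticity(),
        float(pa.charge_at_pH(7.0)),
        float(pa.molar_extinction_coefficient()[0]),
        entropy,
        float(_max_run(s, motif_scan.BASIC)),
        float(_max_run(s, CLASS_SETS["hydrophobic"])),
        helix, turn, sheet,
    ]

    kd_vals = np.array([KD[c] for c in s])
    w = min(HYD_PROFILE_WINDOW, L)
    profile = np.convolve(kd_vals, np.ones(w) / w, mode="valid")
    q25, q50, q75 = np.percentile(profile, [25, 50, 75])
    profile_vals = [
        float(profile.mean()), float(profile.var()),
        float(profile.min()), float(profile.max()),
        float(q25), float(q50), float(q75),
    ]

    fraction_vals = [
        sum(comp[_AA_INDEX[a]] for a in members)
        for members in CLASS_SETS.values()
    ]

    ann = motif_scan.annotate(seq)
    n_single, n_di, n_tri = ann.n_single, ann.n_dibasic, ann.n_tribasic
    eff = ann.effective_length
    motif_starts = sorted(ann.dibasic + ann.tribasic)
    spacing = (float(np.mean(np.diff(motif_starts)))
               if len(motif_starts) >= 2 else 0.0)
    n_nterm = sum(1 for p in motif_starts if p <= TERMINAL_WINDOW)
    motif_vals = [
        float(s.count("K")), float(s.count("R")),
        100.0 * s.count("K") / L, 100.0 * s.count("R") / L,
        float(n_single), float(n_di), float(n_tri),
        100.0 * n_single / L, 100.0 * n_di / L, 100.0 * n_tri / L,
        100.0 * n_single / eff, 100.0 * n_di / eff, 100.0 * n_tri / eff,
        ann.internal_score, spacing, float(n_nterm),
    ]

    nterm = s[:TERMINAL_WINDOW]
    cterm = s[-TERMINAL_WINDOW:]
    n_comp, n_gravy, n_charge, n_run = _window_stats(nterm)
    c_comp, c_gravy, c_charge, _ = _window_stats(cterm)
    c_basic_frac = sum(1 for c in cterm if c in CLASS_SETS["basic"]) / len(cterm)
    term_scalars = [n_gravy, n_charge, float(n_run),
                    c_gravy, c_charge, c_basic_frac]

    cbg = np.zeros(49)
    if L >= 2:
        ridx = np.fromiter((_REDUCED_OF[c] for c in s), dtype=np.intp, count=L)
        pair = ridx[:-1] * 7 + ridx[1:]
        cbg = np.bincount(pair, minlength=49).astype(float) / (L - 1)

    vals = np.concatenate([
        global_vals, profile_vals, fraction_vals, motif_vals,
        n_comp, c_comp, term_scalars, cbg,
    ])
    assert vals.shape == (140,)
    return vals


def extract(seq: ProteinSequence) -> FeatureVector:
    """Full 560-feature vector: composition ∥ bigram ∥ physchem."""
    values = np.concatenate([
        aa_composition(seq),
        bigram_frequencies(seq),
        physchem_features(seq),
    ])
    return FeatureVector(values=values)


def extract_matrix(seqs: Iterable[ProteinSequence]) -> pd.DataFrame:
    """Feature matrix, one row per sequence (row order = input order).

    The index holds sequence ids (duplicates allowed; rows are keyed by
    position).
    """
    seqs = list(seqs)
    mat = np.empty((len(seqs), len(FEATURE_NAMES)))
    for i, seq in enumerate(seqs):
        mat[i] = extract(seq).values
    df = pd.DataFrame(mat, columns=list(FEATURE_NAMES),
                      index=[s.id for s in seqs])
    df.attrs["catalog_version"] = CATALOG_VERSION
    return df


def write_feature_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """TSV export: header of feature names, first column = sequence id."""
    df.to_csv(path, sep="\t", index_label="id")
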