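"""In-silico tryptic digestion, species-uniqueness annotation, protein
inference and ratio statistics for two-species TMT-style quant tables.

Peptides are cut C-terminal of K or R except before P, with up to
``max_missed`` missed cleavages, and retained at a minimum length of seven
residues.  Against a combined two-species database each peptide is unique to
one species or shared; proteins are annotated by their specific peptides and
retained only when supported by at least two unique peptides.  Reporter-ion
signal sums are calibrated per channel (median/MAD matching) and put through
a generalized-log transform for variance stabilization; per-protein log2
ratios against a reference condition are converted to robust z-scores
(median / MAD) with normal p-values and Benjamini-Hochberg q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class PeptideRecord:
    sequence: str
    missed_cleavages: int
    start: int  # 0-based position in the parent protein
    parents: dict[str, list[str]] = field(default_factory=dict)  # species -> proteins
    species_class: str = ""  # A_only / B_only / shared


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

def cleavage_sites(seq: str) -> list[int]:
    """Positions *after* which trypsin cuts: K/R not followed by P."""
    return [i + 1 for i in range(len(seq) - 1)
            if seq[i] in "KR" and seq[i + 1] != "P"]


def digest(seq: str, max_missed: int = 2, min_len: int = 7) -> list[PeptideRecord]:
    """Tryptic peptides of one protein with 0..max_missed missed cleavages."""
    if not seq:
        raise ValueError("empty protein sequence")
    bounds = [0, *cleavage_sites(seq), len(seq)]
    out = []
    for i in range(len(bounds) - 1):
        for m in range(max_missed + 1):
            j = i + 1 + m
            if j >= len(bounds):
                break
            pep = seq[bounds[i]:bounds[j]]
            if len(pep) >= min_len:
                out.append(PeptideRecord(pep, missed_cleavages=m, start=bounds[i]))
    return out


# ---------------------------------------------------------------------------
# species-uniqueness classification
# ---------------------------------------------------------------------------

def build_combined_db(ref_a, ref_b, max_missed: int = 2, min_len: int = 7,
                      il_equivalent: bool = False) -> dict[str, dict[str, set[str]]]:
    """Digest both proteomes identically: peptide -> {species: {proteins}}."""
    db: dict[str, dict[str, set[str]]] = {}
    for ref in (ref_a, ref_b):
        for pid, seq in ref.protein_db.items():
            for pep in digest(seq, max_missed, min_len):
                key = pep.sequence.replace("I", "L") if il_equivalent else pep.sequence
                db.setdefault(key, {}).setdefault(ref.species_label, set()).add(pid)
    return db


def classify_peptides(peptides: list[str] | pd.Series, db: dict,
                      species_a: str, species_b: str,
                      il_equivalent: bool = False) -> pd.Series:
    """Annotate peptide sequences as A_only / B_only / shared / unknown."""
    out = []
    for pep in peptides:
        key = pep.replace("I", "L") if il_equivalent else pep
        hit = db.get(key)
        if hit is None:
            out.append("unknown")
        elif species_a in hit and species_b in hit:
            out.append("shared")
        elif species_a in hit:
            out.append("A_only")
        else:
            out.append("B_only")
    idx = peptides.index if isinstance(peptides, pd.Series) else None
    return pd.Series(out, index=idx, name="species_class")


def species_annotation_counts(quant: pd.DataFrame, db: dict, species_a: str,
                              species_b: str) -> dict[str, int]:
    """Per-category protein counts for one fraction (specific A / B / shared)."""
    cls = classify_peptides(quant["peptide"], db, species_a, species_b)
    per_protein = quant.assign(cls=cls.values).groupby("protein")["cls"].agg(set)
    counts = {"A_specific": 0, "B_specific": 0, "shared": 0}
    for classes in per_protein:
        specific = classes - {"shared", "unknown"}
        if specific == {"A_only"}:
            counts["A_specific"] += 1
        elif specific == {"B_only"}:
            counts["B_specific"] += 1
        else:
            counts["shared"] += 1
    return counts


# ---------------------------------------------------------------------------
# protein inference
# ---------------------------------------------------------------------------

def infer_proteins(quant: pd.DataFrame, db: dict, species_a: str, species_b: str,
                   channels: list[str] | None = None, min_unique: int = 2,
                   il_equivalent: bool = False) -> pd.DataFrame:
    """Protein-level quant from a peptide table.

    ``quant`` needs columns peptide / protein plus one column per channel.
    A protein's species annotation is A when all its detected species-specific
    peptides are A-only (symmetrically B), and shared when only shared
    peptides support it.  Its per-channel signal is the sum over its peptides.
    The unique-peptide count excludes peptides shared across proteins (within
    either species) or across species; proteins below ``min_unique`` are
    dropped.
    """
    channels = channels or [c for c in quant.columns
                            if c not in ("peptide", "protein", "true_species")]
    cls = classify_peptides(quant["peptide"], db, species_a, species_b, il_equivalent)
    q = quant.assign(_cls=cls.values)

    # a peptide is "unique" when it maps to exactly one protein of one species
    def n_proteins(pep: str) -> int:
        key = pep.replace("I", "L") if il_equivalent else pep
        hit = db.get(key, {})
        return sum(len(v) for v in hit.values())

    q["_unique"] = [n_proteins(p) == 1 for p in q["peptide"]]

    rows = []
    for pid, grp in q.groupby("protein", sort=True):
        specific = set(grp.loc[grp["_cls"].isin(["A_only", "B_only"]), "_cls"])
        if specific == {"A_only"}:
            annot = species_a
        elif specific == {"B_only"}:
            annot = species_b
        else:
            annot = "shared"
        n_unique = int(grp.loc[grp["_unique"], "peptide"].nunique())
        sums = grp[channels].sum(axis=0)
        rows.append((pid, annot, n_unique, *sums))
    out = pd.DataFrame(rows, columns=["protein", "species", "unique_peptides", *channels]
                       ).set_index("protein")
    return out[out["unique_peptides"] >= min_unique]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def glog(x: np.ndarray, c: float) -> np.ndarray:
    """Generalized log2: log2((x + sqrt(x^2 + c^2)) / 2); ~log2(x) for x >> c."""
    return np.log2((x + np.sqrt(x * x + c * c)) / 2.0)


def normalize_signals(signals: pd.DataFrame, c: float | None = None) -> pd.DataFrame:
    """Variance-stabilizing normalization of per-channel signal sums.

    Channels are calibrated to a common location/scale by median and MAD
    matching, then transformed with a generalized log (glog).  The glog scale
    ``c`` defaults to the median calibrated signal divided by 100, which
    leaves high-intensity signals on the plain log2 scale.
    """
    if (signals.values <= 0).any():
        raise ValueError("signals must be positive")
    med = signals.median(axis=0)
    mad = (signals - med).abs().median(axis=0)
    target_med, target_mad = float(med.median()), float(mad.median())
    calibrated = signals.copy().astype(float)
    for col in signals.columns:
        scale = target_mad / mad[col] if mad[col] > 0 else 1.0
        calibrated[col] = (signals[col] - med[col]) * scale + target_med
    clipped = calibrated.clip(lower=target_med * 1e-6)
    if c is None:
        c = float(np.median(clipped.values)) / 100.0
    return pd.DataFrame(glog(clipped.values, c), index=signals.index,
                        columns=signals.columns)


# ---------------------------------------------------------------------------
# ratio statistics
# ---------------------------------------------------------------------------

def ratio_stats(normalized: pd.DataFrame, reference: str | list[str]) -> pd.DataFrame:
    """Per-protein log2 ratios vs a reference condition with robust z / p / q.

    The ratio distribution is standardized by its robust location (median)
    and scale (MAD x 1.4826); two-sided p-values come from the standard
    normal and q-values from Benjamini-Hochberg.
    """
    ref_cols = [reference] if isinstance(reference, str) else list(reference)
    missing = set(ref_cols) - set(normalized.columns)
    if missing:
        raise ValueError(f"reference channel(s) absent: {sorted(missing)}")
    ref = normalized[ref_cols].mean(axis=1)
    test_cols = [c for c in normalized.columns if c not in ref_cols]
    frames = []
    for col in test_cols:
        ratio = normalized[col] - ref  # glog/log2 scale: difference = log ratio
        dev = ratio - float(ratio.median())
        mad = float(dev.abs().median())
        if mad == 0:
            if dev.abs().max() < 1e-9:  # constant ratios: no spread, no signal
                z = dev * 0.0
            else:
                raise ValueError(f"degenerate ratio distribution for channel {col} (zero MAD)")
        else:
            z = dev / (mad * 1.4826)
        p = 2.0 * stats.norm.sf(np.abs(z))
        q = multipletests(p, method="fdr_bh")[1]
        frames.append(pd.DataFrame({"channel": col, "log2_ratio": ratio,
                                    "z": z, "p": p, "q": q}))
    return pd.concat(frames)
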