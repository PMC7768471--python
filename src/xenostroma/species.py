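"""k-mer based assignment of mixed reads to species and gene-level counting.

Every canonical (strand-collapsed) k-mer of the two transcript references is
classified as specific to species A, specific to species B, or shared.  A
read is assigned to a species when it carries at least ``min_specific``
k-mers specific to that species and none specific to the other; reads with
specific hits to both species, or only shared hits, are ambiguous; reads
with no hits are unassigned.  Ambiguous and unassigned reads are excluded
from the per-gene count matrices, and the per-sample tally of all four
labels yields the stroma-content statistic (species-B read share).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountMatrix

log = logging.getLogger("xenostroma")

_COMP = str.maketrans("ACGT", "TGCA")


def canonical(kmer: str) -> str:
    rc = kmer.translate(_COMP)[::-1]
    return kmer if kmer <= rc else rc


@dataclass
class SpeciesIndex:
    k: int
    label_a: str
    label_b: str
    # canonical k-mer -> (tuple of A genes, tuple of B genes)
    kmers: dict[str, tuple[tuple[str, ...], tuple[str, ...]]]
    genes_a: list[str]
    genes_b: list[str]

    def classify_kmer(self, kmer: str) -> str:
        hit = self.kmers.get(canonical(kmer))
        if hit is None:
            return "absent"
        a, b = hit
        if a and b:
            return "shared"
        return "A_only" if a else "B_only"


@dataclass
class ReadAssignment:
    read_id: str
    label: str  # A / B / ambiguous / unassigned
    best_gene: str | None
    a_hits: int
    b_hits: int
    shared_hits: int
    sample_id: str = ""


def build_index(ref_a, ref_b, k: int = 21) -> SpeciesIndex:
    """Classify every observed canonical k-mer of the two references."""
    if k < 8:
        raise ValueError("k must be >= 8")
    for ref in (ref_a, ref_b):
        if not ref.genes:
            raise ValueError(f"reference {ref.species_label!r} is empty")
        short = [g for g, s in ref.genes.items() if len(s) < k]
        if short:
            raise ValueError(f"k={k} exceeds transcript length of {short[:3]}")
    acc: dict[str, tuple[set, set]] = {}
    for slot, ref in ((0, ref_a), (1, ref_b)):
        for gene, seq in ref.genes.items():
            for i in range(len(seq) - k + 1):
                km = canonical(seq[i:i + k])
                entry = acc.get(km)
                if entry is None:
                    entry = (set(), set())
                    acc[km] = entry
                entry[slot].add(gene)
    kmers = {km: (tuple(sorted(a)), tuple(sorted(b))) for km, (a, b) in acc.items()}
    return SpeciesIndex(k, ref_a.species_label, ref_b.species_label, kmers,
                        list(ref_a.genes), list(ref_b.genes))


def classify_read(read_id: str, sequence: str, index: SpeciesIndex,
                  min_specific: int = 2, sample_id: str = "") -> ReadAssignment:
    """Assign one read by its species-specific k-mer support.

    Decision rule: A when ``a_hits >= min_specific`` and ``b_hits == 0``
    (symmetrically B); ambiguous when both species have specific hits or only
    shared k-mers match; unassigned when nothing matches.  The best gene is
    the one with most supporting specific k-mers, ties broken by gene id.
    """
    k = index.k
    if len(sequence) < k:
        log.warning("read %s shorter than k=%d: unassigned", read_id, k)
        return ReadAssignment(read_id, "unassigned", None, 0, 0, 0, sample_id)
    a_hits = b_hits = shared = 0
    gene_support_a: Counter = Counter()
    gene_support_b: Counter = Counter()
    for i in range(len(sequence) - k + 1):
        hit = index.kmers.get(canonical(sequence[i:i + k]))
        if hit is None:
            continue
        a, b = hit
        if a and b:
            shared += 1
        elif a:
            a_hits += 1
            gene_support_a.update(a)
        else:
            b_hits += 1
            gene_support_b.update(b)
    if a_hits >= min_specific and b_hits == 0:
        label, support = "A", gene_support_a
    elif b_hits >= min_specific and a_hits == 0:
        label, support = "B", gene_support_b
    elif a_hits == 0 and b_hits == 0 and shared == 0:
        return ReadAssignment(read_id, "unassigned", None, 0, 0, 0, sample_id)
    else:
        return ReadAssignment(read_id, "ambiguous", None, a_hits, b_hits, shared, sample_id)
    best = min((g for g, n in support.items() if n == max(support.values())))
    return ReadAssignment(read_id, label, best, a_hits, b_hits, shared, sample_id)


def classify_reads(reads: pd.DataFrame, index: SpeciesIndex,
                   min_specific: int = 2) -> list[ReadAssignment]:
    """Classify a read table (columns read_id, sequence, sample_id)."""
    return [classify_read(r.read_id, r.sequence, index, min_specific,
                          getattr(r, "sample_id", ""))
            for r in reads.itertuples(index=False)]


def count_by_gene(assignments: list[ReadAssignment], index: SpeciesIndex,
                  meta: pd.DataFrame) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Per-species gene-level count matrices plus the per-sample label tally.

    Ambiguous and unassigned reads are excluded from both matrices but appear
    in the tally, so the tally row sums equal the per-sample read totals.
    """
    samples = list(meta.index)
    ca = pd.DataFrame(0, index=pd.Index(index.genes_a, name="gene"), columns=samples)
    cb = pd.DataFrame(0, index=pd.Index(index.genes_b, name="gene"), columns=samples)
    tally = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"),
                         columns=["A", "B", "ambiguous", "unassigned"])
    for a in assignments:
        tally.loc[a.sample_id, a.label] += 1
        if a.label == "A":
            ca.loc[a.best_gene, a.sample_id] += 1
        elif a.label == "B":
            cb.loc[a.best_gene, a.sample_id] += 1
    return (CountMatrix(ca, meta, index.label_a),
            CountMatrix(cb, meta, index.label_b), tally)


def stroma_fraction(tally: pd.DataFrame) -> pd.Series:
    """Species-B (stroma) share of assigned reads per sample.

    Samples with zero assigned reads get NaN and a warning rather than an
    error.
    """
    assigned = tally["A"] + tally["B"]
    frac = tally["B"] / assigned.where(assigned > 0)
    for s in frac.index[assigned == 0]:
        log.warning("sample %s has no assigned reads: stroma fraction undefined", s)
    return frac.rename("stroma_fraction")
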