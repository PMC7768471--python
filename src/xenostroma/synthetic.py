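"""Synthetic study inputs with known ground truth.

The generator emulates every input of the tumor/stroma deconvolution study:
two-species transcript and protein references with tunable homology, mixed
bulk RNA-seq counts and reads from two PDX models (an androgen-dependent
BM18-like and a castration-resistant LAPC9-like line) under intact /
castrated / androgen-replaced states, human- and mouse-enriched proteomic
fractions with cross-contamination, and a TMA-style survival cohort.

Counts follow a negative-binomial model: for gene g in sample s,

    counts ~ NB(mean = L_s * f_s * w_g * 2^effect(model, condition),  phi)

where L_s is the library size, f_s the compartment fraction (stroma fraction
for the mouse side, 1 - f_s for the human side), w_g a log-normal relative
abundance, and phi the dispersion (phi = 0 degenerates to Poisson).  Planted
androgen-responsive stroma gene sets (the C1-C4 ground truth) enter through
the per-(model, condition) log2 effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CONDITIONS, MODELS, CountMatrix, OrthologTable, SampleMeta, design_frame
from .proteomics import digest

NT = np.array(list("ACGT"))
AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SpeciesReference:
    """Transcript and protein sequences for one species."""

    species_label: str
    genes: dict[str, str]
    protein_db: dict[str, str]

    def __post_init__(self) -> None:
        for gid, seq in self.genes.items():
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"{gid}: nucleotide sequence must be non-empty over ACGT")
        for pid, seq in self.protein_db.items():
            if not seq or set(seq) - set(AA.tolist()):
                raise ValueError(f"{pid}: protein sequence must be non-empty over the 20 aa")

    @property
    def lengths(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.genes.items()}

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)


@dataclass
class PlantedSet:
    """One planted cluster: its genes and per-(model, condition) log2 effects."""

    genes: list[str]
    effects: dict[tuple[str, str], float]  # (model, condition) -> log2 fold


@dataclass
class SimulationTruth:
    planted_sets: dict[str, PlantedSet]
    stroma_fraction: dict[str, float]          # sample_id -> [0, 1]
    dispersion: float | dict[str, float] = 0.1
    library_size: int | dict[str, int] = 5_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for s, f in self.stroma_fraction.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"stroma_fraction[{s}]={f} outside [0, 1]")
        seen: set[str] = set()
        for name, ps in self.planted_sets.items():
            overlap = seen & set(ps.genes)
            if overlap:
                raise ValueError(f"planted gene(s) {sorted(overlap)[:3]} in more than one cluster")
            seen |= set(ps.genes)

    def phi(self, gene: str) -> float:
        if isinstance(self.dispersion, dict):
            return self.dispersion.get(gene, 0.1)
        return float(self.dispersion)

    def lib(self, sample: str) -> int:
        if isinstance(self.library_size, dict):
            return int(self.library_size[sample])
        return int(self.library_size)


@dataclass
class CohortTruth:
    """Parameters of the synthetic TMA-style survival cohort."""

    marker_hazard_ratio: float = 2.5
    censor_rate: float = 0.3
    n_patients: int = 210
    cores_per_patient: int = 4
    gleason_distribution: dict[int, float] = field(
        default_factory=lambda: {6: 0.10, 7: 0.40, 8: 0.25, 9: 0.20, 10: 0.05})
    stage_distribution: dict[str, float] = field(
        default_factory=lambda: {"2a": 7 / 210, "2b": 27 / 210, "3a": 53 / 210,
                                 "3b": 84 / 210, "4": 39 / 210})

    def __post_init__(self) -> None:
        if self.marker_hazard_ratio <= 0:
            raise ValueError("marker_hazard_ratio must be positive")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ValueError("censor_rate must lie in [0, 1]")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.cores_per_patient < 1:
            raise ValueError("need at least 1 core per patient")


# ---------------------------------------------------------------------------
# design and truth defaults
# ---------------------------------------------------------------------------

#: replicates per condition mirroring the study design
DEFAULT_REPLICATES = {"intact": 3, "castrated": 4, "replaced": 3}

#: default stroma fractions; the BM18-like model is stroma-rich and gains
#: stroma after castration, the LAPC9-like model is stroma-poor throughout
DEFAULT_STROMA_FRACTION = {
    ("BM18like", "intact"): 0.3,
    ("BM18like", "castrated"): 0.6,
    ("BM18like", "replaced"): 0.3,
    ("LAPC9like", "intact"): 0.1,
    ("LAPC9like", "castrated"): 0.1,
    ("LAPC9like", "replaced"): 0.1,
}

#: planted cluster sizes mirroring the reported C1-C4 signature sizes
DEFAULT_CLUSTER_SIZES = {"C1": 50, "C2": 27, "C3": 32, "C4": 24}


def default_design(models: tuple[str, ...] = MODELS,
                   replicates: dict[str, int] | None = None) -> list[SampleMeta]:
    """The study design: per model, 3 intact, 4 castrated, 3 replaced."""
    replicates = replicates or DEFAULT_REPLICATES
    design = []
    for model in models:
        for condition in CONDITIONS:
            for r in range(1, replicates.get(condition, 0) + 1):
                design.append(SampleMeta(f"{model}_{condition}_{r}", model, condition, r))
    return design


def default_cluster_effects(effect: float = 3.0, retained: float = 2.2
                            ) -> dict[str, dict[tuple[str, str], float]]:
    """Per-cluster (model, condition) log2 effects.

    The four profiles are chosen so that each extraction rule matches its own
    cluster and no other:

    * C1 - androgen-responsive in the BM18-like stroma: up in intact only.
    * C2 - androgen-responsive in the LAPC9-like stroma but constitutively
      expressed in the BM18-like stroma (so not LAPC9-specific).
    * C3 - LAPC9-enriched at all states, strongest in intact, with a low
      constitutive level in the BM18-like stroma; the castration drop
      (effect - retained) stays below the 2-fold significance filter.
    * C4 - up specifically in the castrated LAPC9-like stroma.
    """
    e, r = float(effect), float(retained)
    base = 0.6  # constitutive BM18-side level of the C3 genes
    return {
        "C1": {("BM18like", "intact"): e},
        "C2": {("BM18like", "intact"): e, ("BM18like", "castrated"): e,
               ("BM18like", "replaced"): e, ("LAPC9like", "intact"): e},
        "C3": {("LAPC9like", "intact"): e, ("LAPC9like", "castrated"): r,
               ("LAPC9like", "replaced"): r, ("BM18like", "intact"): base,
               ("BM18like", "castrated"): base, ("BM18like", "replaced"): base},
        "C4": {("LAPC9like", "castrated"): e},
    }


def default_truth(mouse_genes: list[str], design: list[SampleMeta], seed: int = 0,
                  cluster_sizes: dict[str, int] | None = None,
                  effect: float = 3.0, dispersion: float = 0.1,
                  library_size: int = 5_000_000,
                  stroma_fraction: dict[tuple[str, str], float] | None = None,
                  ) -> SimulationTruth:
    """Assemble the default ground truth over a mouse gene universe."""
    sizes = cluster_sizes or DEFAULT_CLUSTER_SIZES
    total = sum(sizes.values())
    if total > len(mouse_genes):
        raise ValueError("gene universe smaller than the planted clusters")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.asarray(mouse_genes), size=total, replace=False)
    effects = default_cluster_effects(effect=effect)
    planted, at = {}, 0
    for name, size in sizes.items():
        planted[name] = PlantedSet(list(chosen[at:at + size]), effects.get(name, {}))
        at += size
    fracs = stroma_fraction or DEFAULT_STROMA_FRACTION
    sample_frac = {m.sample_id: fracs[(m.model, m.condition)] for m in design}
    return SimulationTruth(planted, sample_frac, dispersion, library_size, seed)


def gene_universe(n: int, prefix: str) -> list[str]:
    """Plain gene-id universe for count-level simulations (no sequences)."""
    return [f"{prefix}{i:05d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# references
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, alphabet: np.ndarray) -> str:
    return "".join(rng.choice(alphabet, size=length))

def _mutate(rng: np.random.Generator, seq: str, identity: float, alphabet: np.ndarray) -> str:
    chars = np.array(list(seq))
    hit = rng.random(len(chars)) < (1.0 - identity)
    for i in np.nonzero(hit)[0]:
        options = alphabet[alphabet != chars[i]]
        chars[i] = rng.choice(options)
    return "".join(chars)


def make_references(n_specific_a: int, n_specific_b: int, n_homolog_pairs: int,
                    homolog_identity: float, seed: int = 0,
                    gene_length: tuple[int, int] = (400, 800),
                    protein_length: tuple[int, int] = (200, 400),
                    n_decoys: int = 0,
                    labels: tuple[str, str] = ("human", "mouse"),
                    ) -> tuple[SpeciesReference, SpeciesReference, OrthologTable]:
    """Two-species references with seeded homology and an ortholog table.

    Homolog pairs share per-base identity ``homolog_identity`` at both the
    nucleotide and amino-acid level; species-specific genes share no seeded
    homology.  The ortholog table lists the homolog pairs with confidence 1
    plus ``n_decoys`` confidence-0 decoy pairs of species-specific genes.
    """
    if not (0.0 <= homolog_identity <= 1.0):
        raise ValueError("homolog_identity must lie in [0, 1]")
    if min(n_specific_a, n_specific_b, n_homolog_pairs) < 0:
        raise ValueError("gene counts must be non-negative")
    if n_specific_a + n_specific_b + n_homolog_pairs == 0:
        raise ValueError("references need at least one gene")
    rng = np.random.default_rng(seed)
    la, lb = labels
    pa, pb = la[:3].upper(), lb[:3].upper()

    genes_a, genes_b, prot_a, prot_b = {}, {}, {}, {}
    for i in range(n_specific_a):
        gid = f"{pa}_S{i + 1:04d}"
        genes_a[gid] = _random_seq(rng, rng.integers(*gene_length), NT)
        prot_a[gid] = _random_seq(rng, rng.integers(*protein_length), AA)
    for i in range(n_specific_b):
        gid = f"{pb}_S{i + 1:04d}"
        genes_b[gid] = _random_seq(rng, rng.integers(*gene_length), NT)
        prot_b[gid] = _random_seq(rng, rng.integers(*protein_length), AA)
    rows = []
    for i in range(n_homolog_pairs):
        ga, gb = f"{pa}_H{i + 1:04d}", f"{pb}_H{i + 1:04d}"
        nt = _random_seq(rng, rng.integers(*gene_length), NT)
        aa = _random_seq(rng, rng.integers(*protein_length), AA)
        genes_a[ga], genes_b[gb] = nt, _mutate(rng, nt, homolog_identity, NT)
        prot_a[ga], prot_b[gb] = aa, _mutate(rng, aa, homolog_identity, AA)
        rows.append((gb, ga, 1))
    for i in range(min(n_decoys, n_specific_a, n_specific_b)):
        rows.append((f"{pb}_S{i + 1:04d}", f"{pa}_S{i + 1:04d}", 0))
    table = OrthologTable(pd.DataFrame(rows, columns=["mouse_gene", "human_gene", "confidence"]))
    return (SpeciesReference(la, genes_a, prot_a),
            SpeciesReference(lb, genes_b, prot_b), table)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mean, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        r = 1.0 / phi[~pois]
        m = mean[~pois]
        out[~pois] = rng.negative_binomial(r, r / (r + m))
    return out


def _universe(ref) -> list[str]:
    return ref.gene_ids if hasattr(ref, "gene_ids") else list(ref)


def simulate_counts(ref_human, ref_mouse, design: list[SampleMeta], truth: SimulationTruth,
                    ) -> tuple[CountMatrix, CountMatrix, CountMatrix]:
    """Simulate (human, mouse, mixed) count matrices for one design.

    ``ref_human`` / ``ref_mouse`` may be :class:`SpeciesReference` objects or
    plain gene-id lists.  The mixed matrix is the exact row-wise union of the
    two species matrices (gene ids are disjoint), so conservation holds by
    construction.
    """
    genes_h, genes_m = _universe(ref_human), _universe(ref_mouse)
    for ps in truth.planted_sets.values():
        missing = set(ps.genes) - set(genes_m)
        if missing:
            raise ValueError(f"planted gene(s) not in the mouse universe: {sorted(missing)[:3]}")
    meta = design_frame(design)
    rng = np.random.default_rng(truth.seed)

    # background relative abundances: log-normal, sigma = 1
    rel_h = rng.lognormal(0.0, 1.0, len(genes_h))
    rel_m = rng.lognormal(0.0, 1.0, len(genes_m))
    phi_h = np.array([truth.phi(g) for g in genes_h])
    phi_m = np.array([truth.phi(g) for g in genes_m])

    m_idx = {g: i for i, g in enumerate(genes_m)}
    effect_cache: dict[tuple[str, str], np.ndarray] = {}
    for model in {m.model for m in design}:
        for condition in {m.condition for m in design}:
            eff = np.zeros(len(genes_m))
            for ps in truth.planted_sets.values():
                lfc = ps.effects.get((model, condition), 0.0)
                if lfc:
                    eff[[m_idx[g] for g in ps.genes]] = lfc
            effect_cache[(model, condition)] = eff

    ch, cm = {}, {}
    for s in design:
        f = truth.stroma_fraction[s.sample_id]
        lib = truth.lib(s.sample_id)
        w_h = rel_h / rel_h.sum()
        w_m = rel_m * np.exp2(effect_cache[(s.model, s.condition)])
        w_m = w_m / w_m.sum()
        mean_h = (1.0 - f) * lib * w_h
        mean_m = f * lib * w_m
        ch[s.sample_id] = _nb_draw(rng, mean_h, phi_h)
        cm[s.sample_id] = _nb_draw(rng, mean_m, phi_m)

    human = CountMatrix(pd.DataFrame(ch, index=pd.Index(genes_h, name="gene")), meta, "human")
    mouse = CountMatrix(pd.DataFrame(cm, index=pd.Index(genes_m, name="gene")), meta, "mouse")
    mixed = CountMatrix(pd.concat([human.counts, mouse.counts]), meta, "mixed")
    return human, mouse, mixed


def truth_table(truth: SimulationTruth) -> pd.DataFrame:
    """Planted-gene truth as a flat table (gene, cluster)."""
    rows = [(g, name) for name, ps in truth.planted_sets.items() for g in ps.genes]
    return pd.DataFrame(rows, columns=["gene", "cluster"])


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def simulate_reads(ref_a: SpeciesReference, ref_b: SpeciesReference,
                   weights: dict[str, float], read_length: int, error_rate: float,
                   n_reads: int, seed: int = 0, sample_id: str = "S1") -> pd.DataFrame:
    """Reads from a per-sample expression mixture over both references.

    Each read records its hidden truth (species, gene).  Substitution errors
    are independent per base at ``error_rate``; strands are sampled uniformly.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    source = {}
    for ref in (ref_a, ref_b):
        for g, s in ref.genes.items():
            source[g] = (ref.species_label, s)
    genes = [g for g in weights if weights[g] > 0]
    if not genes:
        raise ValueError("no gene with positive expression weight")
    min_len = min(len(source[g][1]) for g in genes)
    if read_length > min_len:
        raise ValueError(f"read_length {read_length} exceeds shortest transcript ({min_len})")
    w = np.array([weights[g] for g in genes], dtype=float)
    w /= w.sum()
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(genes), size=n_reads, p=w)
    rows = []
    for i, gi in enumerate(pick):
        gene = genes[gi]
        species, seq = source[gene]
        start = rng.integers(0, len(seq) - read_length + 1)
        read = seq[start:start + read_length]
        if rng.random() < 0.5:
            read = revcomp(read)
        if error_rate > 0:
            chars = np.array(list(read))
            hit = rng.random(read_length) < error_rate
            for j in np.nonzero(hit)[0]:
                chars[j] = rng.choice(NT[NT != chars[j]])
            read = "".join(chars)
        rows.append((f"{sample_id}_r{i + 1}", read, sample_id, species, gene))
    return pd.DataFrame(rows, columns=["read_id", "sequence", "sample_id",
                                       "true_species", "true_gene"])


def expression_weights(counts: CountMatrix, sample_id: str) -> dict[str, float]:
    col = counts.counts[sample_id]
    return {g: float(v) for g, v in col.items() if v > 0}


# ---------------------------------------------------------------------------
# proteomics
# ---------------------------------------------------------------------------

DEFAULT_CHANNELS = [f"{m}_{c}" for m in MODELS for c in CONDITIONS]


def default_protein_abundance(ref_a: SpeciesReference, ref_b: SpeciesReference,
                              channels: list[str] | None = None, seed: int = 0,
                              ) -> pd.DataFrame:
    """Log-normal baseline protein abundances, constant across channels."""
    channels = channels or DEFAULT_CHANNELS
    rng = np.random.default_rng(seed)
    prots = list(ref_a.protein_db) + list(ref_b.protein_db)
    base = rng.lognormal(8.0, 1.0, len(prots))
    return pd.DataFrame({ch: base for ch in channels},
                        index=pd.Index(prots, name="protein"))


def simulate_proteomics(ref_a: SpeciesReference, ref_b: SpeciesReference,
                        abundance: pd.DataFrame, contamination_rate: float,
                        channel_noise_sd: float, seed: int = 0,
                        min_len: int = 7, secreted: dict[str, float] | None = None,
                        ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Peptide-level quant tables for a human- and a mouse-enriched fraction.

    In each fraction the opposite species contributes ``contamination_rate``
    of the total signal.  Channel noise is log-normal with the given sd (on
    the natural-log scale).  ``secreted`` maps protein ids to an extra signal
    level placed in the *other* species' fraction regardless of purity,
    emulating secreted markers that cross the cell-sorting boundary.

    Returns ``(fractions, truth)`` where ``fractions`` maps fraction name to
    a peptide-level table (peptide, protein, true_species, one column per
    channel) and ``truth`` records the designed per-protein abundances.
    """
    if not (0.0 <= contamination_rate < 0.5):
        raise ValueError("contamination_rate must lie in [0, 0.5)")
    if not len(ref_a.protein_db) or not len(ref_b.protein_db):
        raise ValueError("both proteomes must be non-empty")
    secreted = secreted or {}
    rng = np.random.default_rng(seed)
    channels = list(abundance.columns)
    species_of = {p: ref_a.species_label for p in ref_a.protein_db}
    species_of.update({p: ref_b.species_label for p in ref_b.protein_db})

    tot = {lab: float(abundance.loc[[p for p in abundance.index
                                     if species_of[p] == lab]].values.sum())
           for lab in (ref_a.species_label, ref_b.species_label)}

    fractions = {}
    for own, other, ref_own, ref_other in (
            (ref_a.species_label, ref_b.species_label, ref_a, ref_b),
            (ref_b.species_label, ref_a.species_label, ref_b, ref_a)):
        c = contamination_rate
        beta = 0.0 if c == 0 else c * tot[own] / ((1.0 - c) * tot[other])
        rows = []
        for ref, scale in ((ref_own, 1.0), (ref_other, beta)):
            for pid, seq in ref.protein_db.items():
                extra = secreted.get(pid, 0.0) if ref is ref_other else 0.0
                eff = scale + extra
                if eff <= 0:
                    continue
                peps = [p.sequence for p in digest(seq, max_missed=0, min_len=min_len)]
                if not peps:
                    continue
                ab = abundance.loc[pid, channels].to_numpy(dtype=float) * eff / len(peps)
                for pep in peps:
                    noise = (np.exp(rng.normal(0.0, channel_noise_sd, len(channels)))
                             if channel_noise_sd > 0 else np.ones(len(channels)))
                    rows.append((pep, pid, species_of[pid], *(ab * noise)))
        fractions[f"{own}_enriched"] = pd.DataFrame(
            rows, columns=["peptide", "protein", "true_species", *channels])

    truth = abundance.copy()
    truth.insert(0, "species", [species_of[p] for p in truth.index])
    return fractions, truth


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

def simulate_cohort(truth: CohortTruth, seed: int = 0) -> pd.DataFrame:
    """Raw clinical rows for a TMA-style cohort.

    Per patient: a latent marker group (high with probability 1/2) shifts the
    log-normal per-core marker level; PSA progression, metastasis, local
    recurrence and death times are exponential with the group hazard scaled
    by ``marker_hazard_ratio``; censoring is independent.  The returned frame
    feeds :func:`xenostroma.survival.derive_endpoints`.
    """
    rng = np.random.default_rng(seed)
    n, k = truth.n_patients, truth.cores_per_patient
    hr = truth.marker_hazard_ratio

    group = rng.random(n) < 0.5
    cores = rng.lognormal(np.where(group, 4.3, 3.0)[:, None], 0.5, (n, k))
    gl_keys = np.array(sorted(truth.gleason_distribution))
    gl_p = np.array([truth.gleason_distribution[g] for g in gl_keys], dtype=float)
    st_keys = np.array(sorted(truth.stage_distribution))
    st_p = np.array([truth.stage_distribution[s] for s in st_keys], dtype=float)
    gleason = rng.choice(gl_keys, size=n, p=gl_p / gl_p.sum())
    stage = rng.choice(st_keys, size=n, p=st_p / st_p.sum())

    # baseline monthly hazards per event type (PSA recurrence most frequent)
    base = {"psa": 1 / 80.0, "met": 1 / 250.0, "lr": 1 / 400.0, "os": 1 / 300.0}
    horizon = 150.0  # months of follow-up
    rows = {}
    hazard_scale = np.where(group, hr, 1.0)
    for name, lam in base.items():
        t = rng.exponential(1.0 / (lam * hazard_scale))
        event = np.ones(n, dtype=int)
        if truth.censor_rate > 0:
            censored = rng.random(n) < truth.censor_rate
            t_c = rng.uniform(0, t)
            t = np.where(censored, t_c, t)
            event = np.where(censored, 0, 1)
        over = t > horizon
        t, event = np.where(over, horizon, t), np.where(over, 0, event)
        rows[f"{name}_time"] = t
        rows[f"{name}_event"] = event

    df = pd.DataFrame(rows, index=pd.Index([f"P{i + 1:03d}" for i in range(n)], name="patient_id"))
    for j in range(k):
        df[f"core_{j + 1}"] = cores[:, j]
    df["marker"] = cores.mean(axis=1)
    df["gleason"] = gleason
    df["stage"] = stage
    df["true_group"] = np.where(group, "high", "low")
    df = df.rename(columns={"psa_time": "psa_rec_time", "psa_event": "psa_rec_event",
                            "met_time": "metastasis_time", "met_event": "metastasis_event",
                            "lr_time": "local_rec_time", "lr_event": "local_rec_event",
                            "os_time": "os_time", "os_event": "os_event"})
    df["last_followup"] = df[["psa_rec_time", "metastasis_time",
                              "local_rec_time", "os_time"]].max(axis=1)
    return df
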