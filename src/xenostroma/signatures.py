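"""Extraction of the androgen-dependent stroma signatures C1-C4, ortholog
mapping, and the packaged seven-gene osteoblastic bone-metastasis stroma
(Ob-BMST) signature.

The cluster rules combine a z-score criterion on the stroma expression
matrix with the strict differential-expression significance filter:

* C1 - genes with mean z-score > 1 over the intact replicates of the
  androgen-dependent (BM18-like) model that are significantly DOWN after
  castration (castrated vs intact contrast).
* C2 - the same rule on the castration-resistant (LAPC9-like) model, with
  castrated and androgen-replaced samples pooled as the low group.
* C3 - genes significantly UP in LAPC9-like intact vs BM18-like intact with
  mean z-score > 1 over the LAPC9-like intact samples of the cross-model
  z-matrix.
* C4 - the same cross-model rule at the castrated state (baseline
  configurable to the intact state).
"""

from __future__ import annotations

import logging
from importlib import resources

import pandas as pd

from .containers import CountMatrix, GeneSet, OrthologTable
from .expression import (DEResult, NormalizationFactors, cpm_log2, nb_ql_test,
                         significant, tmm_factors, zscore_matrix)

log = logging.getLogger("xenostroma")


def _mean_condition_z(zmat: pd.DataFrame, meta: pd.DataFrame, model: str,
                      condition: str) -> pd.Series:
    cols = meta.index[(meta["model"] == model) & (meta["condition"] == condition)]
    if len(cols) == 0:
        raise ValueError(f"no {model}/{condition} samples in the z-matrix")
    return zmat[list(cols)].mean(axis=1)


def _rule(de: DEResult, zbar: pd.Series, direction: int, fdr: float, fold: float,
          name: str, species: str, note: str) -> GeneSet:
    sig = significant(de, fdr=fdr, fold=fold)
    lfc = de.table["log2FC"]
    directed = [g for g in sig if direction * lfc[g] > 0]
    members = sorted(g for g in directed if g in zbar.index and zbar[g] > 1.0)
    return GeneSet(name, members, species=species, note=note)


def extract_c1(de: DEResult, zmat: pd.DataFrame, meta: pd.DataFrame,
               model: str = "BM18like", fdr: float = 0.05, fold: float = 2.0) -> GeneSet:
    """Genes up in the intact androgen-dependent stroma, down upon castration.

    ``de`` is the castrated-vs-intact contrast for ``model``; ``zmat`` is the
    per-gene z-score matrix over that model's samples.
    """
    zbar = _mean_condition_z(zmat, meta, model, "intact")
    return _rule(de, zbar, direction=-1, fdr=fdr, fold=fold, name="C1",
                 species="mouse", note=f"intact z>1 and castration-down in {model}")


def extract_c2(de: DEResult, zmat: pd.DataFrame, meta: pd.DataFrame,
               model: str = "LAPC9like", fdr: float = 0.05, fold: float = 2.0) -> GeneSet:
    """The C1 rule on the castration-resistant model with castrated and
    replaced samples pooled against intact."""
    zbar = _mean_condition_z(zmat, meta, model, "intact")
    gs = _rule(de, zbar, direction=-1, fdr=fdr, fold=fold, name="C2",
               species="mouse", note=f"intact z>1 and castration-down in {model}")
    return gs


def extract_c3(de: DEResult, zmat: pd.DataFrame, meta: pd.DataFrame,
               model_high: str = "LAPC9like", fdr: float = 0.05, fold: float = 2.0) -> GeneSet:
    """Genes up in LAPC9-like intact stroma relative to BM18-like intact."""
    zbar = _mean_condition_z(zmat, meta, model_high, "intact")
    return _rule(de, zbar, direction=+1, fdr=fdr, fold=fold, name="C3",
                 species="mouse", note=f"up in {model_high} intact, cross-model")


def extract_c4(de: DEResult, zmat: pd.DataFrame, meta: pd.DataFrame,
               model_high: str = "LAPC9like", state: str = "castrated",
               fdr: float = 0.05, fold: float = 2.0) -> GeneSet:
    """Genes up in LAPC9-like castrated stroma in the cross-model contrast.

    ``state`` is the LAPC9-like condition scored by the z criterion; the
    baseline side of the contrast is carried by ``de``.
    """
    zbar = _mean_condition_z(zmat, meta, model_high, state)
    return _rule(de, zbar, direction=+1, fdr=fdr, fold=fold, name="C4",
                 species="mouse", note=f"up in {model_high} {state}, cross-model")


# ---------------------------------------------------------------------------
# convenience drivers on count matrices
# ---------------------------------------------------------------------------

def stroma_signatures(mouse: CountMatrix, fdr: float = 0.05, fold: float = 2.0,
                      prior_df: float = 10.0, c4_baseline: str = "castrated",
                      ) -> dict[str, GeneSet]:
    """Run all four extraction rules on a two-model stroma count matrix.

    Within-model contrasts are TMM-normalized per model; cross-model
    contrasts are TMM-normalized jointly over both models.  The z-matrix for
    the within-model rules covers that model's samples; for the cross-model
    rules it covers all samples.
    """
    meta = mouse.meta
    out: dict[str, GeneSet] = {}

    def de_for(cm: CountMatrix, groups: pd.Series, contrast) -> DEResult:
        return nb_ql_test(cm, tmm_factors(cm), groups, contrast, prior_df=prior_df)

    # within-model rules
    for name, model, extractor, pool_replaced in (
            ("C1", "BM18like", extract_c1, False),
            ("C2", "LAPC9like", extract_c2, True)):
        cols = meta.index[meta["model"] == model]
        cm = CountMatrix(mouse.counts[list(cols)], meta.loc[cols], mouse.species)
        zmat = zscore_matrix(cpm_log2(cm, tmm_factors(cm)))
        cond = cm.meta["condition"]
        if pool_replaced:
            groups = cond.replace({"replaced": "castrated"})
            used = cm.samples
        else:
            used = cm.samples[cond != "replaced"]
            groups = cond
        sub = CountMatrix(cm.counts[list(used)], cm.meta.loc[used], cm.species)
        de = de_for(sub, groups.loc[used], ("castrated", "intact"))
        out[name] = extractor(de, zmat, cm.meta, model=model, fdr=fdr, fold=fold)

    # cross-model rules on jointly normalized counts
    joint_factors = tmm_factors(mouse)
    zmat_all = zscore_matrix(cpm_log2(mouse, joint_factors))
    for name, state in (("C3", "intact"), ("C4", c4_baseline)):
        la_state = "intact" if name == "C3" else "castrated"
        cols = meta.index[((meta["model"] == "LAPC9like") & (meta["condition"] == la_state)) |
                          ((meta["model"] == "BM18like") & (meta["condition"] == state))]
        sub = CountMatrix(mouse.counts[list(cols)], meta.loc[cols], mouse.species)
        groups = sub.meta["model"]
        sub_factors = NormalizationFactors(
            joint_factors.factors.loc[list(cols)], joint_factors.ref_sample)
        de = nb_ql_test(sub, sub_factors, groups, ("LAPC9like", "BM18like"),
                        prior_df=prior_df)
        if name == "C3":
            out[name] = extract_c3(de, zmat_all, meta, fdr=fdr, fold=fold)
        else:
            out[name] = extract_c4(de, zmat_all, meta, state=la_state, fdr=fdr, fold=fold)
    return out


# ---------------------------------------------------------------------------
# ortholog mapping and fixtures
# ---------------------------------------------------------------------------

def map_orthologs(geneset: GeneSet, table: OrthologTable) -> GeneSet:
    """Map a mouse gene set to human symbols via confidence-1 pairs only.

    Unmapped genes are dropped with a log entry; duplicate human targets are
    collapsed.  Mapping an already-mapped (human) set yields an empty set,
    which is flagged rather than silently returned.
    """
    confident = table.confident()
    lut = dict(zip(confident["mouse_gene"], confident["human_gene"]))
    mapped, dropped = [], []
    for g in geneset.members:
        if g in lut:
            mapped.append(lut[g])
        else:
            dropped.append(g)
    if dropped:
        log.info("map_orthologs(%s): dropped %d unmapped gene(s): %s%s",
                 geneset.name, len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
    if geneset.members and not mapped:
        log.warning("map_orthologs(%s): no gene mapped; input may already be %s",
                    geneset.name, "human")
    unique = list(dict.fromkeys(mapped))
    return GeneSet(geneset.name, unique, species="human",
                   note=f"orthologs of {geneset.name} ({geneset.species})")


def load_ob_bmst() -> GeneSet:
    """The curated seven-gene osteoblastic bone-metastasis stroma signature."""
    text = resources.files("xenostroma").joinpath("data/ob_bmst.gmt").read_text()
    parts = text.strip().split("\t")
    if len(parts) < 3 or parts[0] != "ObBMST":
        raise ValueError("Ob-BMST fixture is corrupt")
    members = parts[2:]
    if len(members) != 7:
        raise ValueError(f"Ob-BMST fixture must list exactly 7 genes, found {len(members)}")
    return GeneSet("ObBMST", members, species="mouse", note=parts[1])
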