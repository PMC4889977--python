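"""Cumulative sex bias of trait-associated variants' eQTL effects.

For each trait, GWAS hits are LD-pruned (greedy by association p, keeping
variants with r^2 < 0.5 to everything already kept).  Each kept variant's
absolute cis effect on expression is estimated separately in males and in
an equally sized random female subsample; a variant is sex-biased when one
sex's |effect| is at least 1.2-fold the other's (boundary inclusive).  Per
trait, a two-sided exact binomial test asks whether female- and male-biased
variants split evenly, with Bonferroni correction across traits.  Traits
with fewer than 20 tested variants are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dataio, eqtl, stats
from .dataio import FEMALE, MALE, ExpressionMatrix, GeneAnnotation, GenotypeMatrix, GwasCatalog
from .sexdiff import match_subsample

logger = logging.getLogger(__name__)

FEMALE_BIASED, MALE_BIASED, UNBIASED = "female", "male", "none"


def r2_from_genotypes(genotypes: GenotypeMatrix, variant_ids: list[str]
                      ) -> dict[tuple[str, str], float]:
    """Pairwise dosage r^2 for the listed variants (complete-case corr^2)."""
    rows = {}
    for v in variant_ids:
        try:
            rows[v] = genotypes.row(v)
        except KeyError:
            continue
    out: dict[tuple[str, str], float] = {}
    ids = list(rows)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            ok = ~np.isnan(rows[a]) & ~np.isnan(rows[b])
            if ok.sum() < 3 or np.std(rows[a][ok]) == 0 or np.std(rows[b][ok]) == 0:
                r2 = 0.0
            else:
                r2 = float(np.corrcoef(rows[a][ok], rows[b][ok])[0, 1] ** 2)
            out[tuple(sorted((a, b)))] = r2
    return out


def ld_prune(trait_rows: pd.DataFrame, r2: dict[tuple[str, str], float],
             r2_max: float = 0.5) -> list[str]:
    """Greedy LD pruning: sort by gwas_p ascending (tie-break variant_id),
    keep a variant iff r^2 < r2_max with every already-kept variant.

    Missing r^2 entries count as 0 (independent) with a warning counter.
    The result is independent of input row order.
    """
    df = trait_rows.sort_values(["gwas_p", "variant_id"], kind="mergesort")
    kept: list[str] = []
    n_missing = 0
    for v in df["variant_id"]:
        ok = True
        for u in kept:
            key = tuple(sorted((u, v)))
            if key not in r2:
                n_missing += 1
                continue
            if r2[key] >= r2_max:
                ok = False
                break
        if ok:
            kept.append(v)
    if n_missing:
        logger.warning("ld_prune: %d missing r^2 pairs treated as 0", n_missing)
    return kept


def per_sex_effects(variant_id: str, genotypes: GenotypeMatrix,
                    expression: ExpressionMatrix, annotation: GeneAnnotation,
                    window: float = 1e6, seed: int = 0,
                    eqtl_p_gate: float = 1e-3,
                    all_genes: bool = False) -> list[dict]:
    """Stratified |effect size| of a variant on cis gene expression.

    The joint additive model picks the best cis gene for the variant (or
    every cis gene when ``all_genes``); the variant must pass the joint
    nominal eQTL significance gate.  Effects are then refit in males and in
    a seeded female subsample matched to the male count.  Returns one dict
    per scored gene; empty when no cis gene qualifies.
    """
    vi = np.flatnonzero(genotypes.variant_ids == variant_id)
    if vi.size == 0:
        raise KeyError(variant_id)
    vi = int(vi[0])
    vpos, vchrom = genotypes.pos[vi], genotypes.chrom[vi]
    w = int(window)
    ann = annotation.table
    cis = ann[(ann["chrom"] == vchrom) & (ann["tss"] - w <= vpos)
              & (vpos <= ann["tes"] + w)]
    gene_index = {g: i for i, g in enumerate(expression.gene_ids)}
    cis = cis[cis["gene_id"].isin(gene_index)]
    if cis.empty:
        logger.info("variant %s: no expressed cis gene; skipped", variant_id)
        return []
    sex = genotypes.samples.sex
    d = genotypes.dosage[vi]
    joint = []
    for gid in cis["gene_id"]:
        y = expression.values[gene_index[gid]]
        try:
            rec = eqtl.fit_additive(y, d, sex, gid, variant_id)
        except (ValueError, np.linalg.LinAlgError):
            continue
        joint.append(rec)
    if not joint:
        return []
    joint.sort(key=lambda r: (r.p, r.gene_id))
    chosen = joint if all_genes else joint[:1]

    males = np.flatnonzero(sex == MALE)
    idx = match_subsample(sex, seed)
    females = idx[sex[idx] == FEMALE]
    out = []
    for rec in chosen:
        if rec.p >= eqtl_p_gate:
            continue
        y = expression.values[gene_index[rec.gene_id]]
        try:
            bm = eqtl.fit_additive(y[males], d[males], None, rec.gene_id,
                                   variant_id, eqtl.MALE_STRATUM)
            bf = eqtl.fit_additive(y[females], d[females], None, rec.gene_id,
                                   variant_id, eqtl.FEMALE_STRATUM)
        except (ValueError, np.linalg.LinAlgError):
            continue
        out.append({"variant_id": variant_id, "gene_id": rec.gene_id,
                    "joint_p": rec.p, "abs_beta_m": abs(bm.beta1),
                    "abs_beta_f": abs(bf.beta1)})
    return out


def classify_bias(abs_beta_m: float, abs_beta_f: float,
                  fold: float = 1.2) -> str:
    """Sex-bias call: 'female' iff |b_f| >= fold*|b_m|, 'male' symmetric,
    else 'none'.  The boundary (exactly ``fold``) counts as biased."""
    if not (np.isfinite(abs_beta_m) and np.isfinite(abs_beta_f)):
        raise ValueError("effects must be finite")
    if abs_beta_m == 0 and abs_beta_f == 0:
        return UNBIASED
    if abs_beta_f >= fold * abs_beta_m:
        return FEMALE_BIASED
    if abs_beta_m >= fold * abs_beta_f:
        return MALE_BIASED
    return UNBIASED


@dataclass
class TraitBiasResult:
    trait: str
    n_tested: int
    n_female: int
    n_male: int
    n_none: int
    p: float
    p_bonf: float
    direction: str
    note: str = ""


def trait_bias_test(classified: pd.DataFrame, min_variants: int = 20
                    ) -> pd.DataFrame:
    """Per-trait exact binomial test of female- vs male-biased counts.

    ``classified`` columns: trait, variant_id, bias.  Traits with fewer than
    ``min_variants`` tested variants are excluded; Bonferroni runs across
    the tested traits.  A trait with zero biased variants reports p = 1
    with a note.
    """
    rows = []
    for trait, sub in classified.groupby("trait", sort=True):
        n = len(sub)
        if n < min_variants:
            logger.info("trait %s: %d < %d variants; excluded", trait, n,
                        min_variants)
            continue
        nf = int((sub["bias"] == FEMALE_BIASED).sum())
        nm = int((sub["bias"] == MALE_BIASED).sum())
        nn = n - nf - nm
        if nf + nm == 0:
            rows.append(TraitBiasResult(trait, n, nf, nm, nn, 1.0, 1.0,
                                        UNBIASED, "no biased variants"))
            continue
        res = stats.binomial_exact(nf, nf + nm, 0.5, stats.TWO_SIDED)
        direction = FEMALE_BIASED if nf > nm else (MALE_BIASED if nm > nf
                                                   else UNBIASED)
        rows.append(TraitBiasResult(trait, n, nf, nm, nn, res.p_value,
                                    np.nan, direction))
    cols = ["trait", "n_tested", "n_female", "n_male", "n_none", "p",
            "p_bonf", "direction", "note"]
    out = pd.DataFrame([vars(r) for r in rows], columns=cols)
    if len(out):
        out["p_bonf"] = np.minimum(1.0, out["p"] * len(out))
    return out


def trait_bias_scan(catalog: GwasCatalog, genotypes: GenotypeMatrix,
                    expression: ExpressionMatrix, annotation: GeneAnnotation,
                    window: float = 1e6, seed: int = 0, r2_max: float = 0.5,
                    fold: float = 1.2, eqtl_p_gate: float = 1e-3,
                    min_variants: int = 20, add_random_control: int = 0
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end trait analysis: prune, score per-sex effects, classify,
    and test each trait.  Returns (per-variant classification, per-trait
    results).  ``add_random_control`` > 0 appends an "RND" pseudo-trait of
    that many randomly chosen variants as a negative control."""
    cat = catalog.table.copy()
    if add_random_control:
        rng = np.random.default_rng(seed + 1)
        pick = rng.choice(genotypes.variant_ids, size=add_random_control,
                          replace=False)
        rnd = pd.DataFrame({
            "trait": "RND", "variant_id": pick,
            "gwas_p": 1e-9,
            "chrom": [genotypes.chrom[np.flatnonzero(
                genotypes.variant_ids == v)[0]] for v in pick],
            "pos": [genotypes.pos[np.flatnonzero(
                genotypes.variant_ids == v)[0]] for v in pick]})
        cat = pd.concat([cat, rnd], ignore_index=True)
    var_rows = []
    for trait, sub in cat.groupby("trait", sort=True):
        r2 = r2_from_genotypes(genotypes, sub["variant_id"].tolist())
        kept = ld_prune(sub, r2, r2_max)
        for v in kept:
            effects = per_sex_effects(v, genotypes, expression, annotation,
                                      window, seed, eqtl_p_gate)
            for e in effects:
                e["trait"] = trait
                e["bias"] = classify_bias(e["abs_beta_m"], e["abs_beta_f"], fold)
                var_rows.append(e)
    classified = pd.DataFrame(var_rows, columns=[
        "trait", "variant_id", "gene_id", "joint_p", "abs_beta_m",
        "abs_beta_f", "bias"])
    results = trait_bias_test(classified, min_variants)
    return classified, results
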