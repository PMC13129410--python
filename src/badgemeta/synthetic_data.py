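"""Synthetic inputs with known truth: trees, effect tables, and the d-bug study.

Three generators cover every stage of the pipeline:

* :func:`simulate_rbis_comparison` reproduces the two-group simulation that
  quantifies the missing-parentheses bug in the biserial computation: both
  groups are drawn from the configured normals, the corrected and the buggy
  conversion are applied to each replicate, and their distributions compared.

* :func:`simulate_tree` draws a random rooted binary topology by sequential
  random joins and assigns Grafen branch lengths, standing in for a published
  phylogeny.

* :func:`simulate_meta_dataset` draws a full multilevel meta-analytic dataset
  with known grand mean and variance components (study, species, phylogeny,
  unit), then emits *raw* per-effect summary statistics for a configurable
  mixture of origins (Pearson r, means-SD-n, t, F, chi-square), so that the
  complete conversion pipeline is exercised end to end.  Each origin's raw
  data are generated on the scale its conversion consistently estimates (the
  latent correlation for r and the biserial; the attenuation-free
  standardized difference for t and F; a 2x2 table whose phi coefficient
  equals the true correlation for chi-square), so the pooled estimate is an
  unbiased target for recovery tests.  Real datasets offer no such guarantee
  -- that mismatch across origins is precisely what the origin moderator
  analysis is for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from . import effect_sizes as es
from .effect_sizes import GroupSummary, Origin
from .meta_engine import MetaDataset, build_sampling_vcv
from .phylo import Phylogeny, PhyloCorrelation, correlation_matrix, grafen_lengths

#: hard clamp for true correlations so finite-sample statistics stay defined
RHO_CLAMP = 0.97

DEFAULT_ORIGIN_MIXTURE = {
    Origin.PEARSON_R: 0.15,
    Origin.MEANS_SD_N: 0.25,
    Origin.T_VALUE: 0.25,
    Origin.F_VALUE: 0.20,
    Origin.CHI2_VALUE: 0.15,
}

DEFAULT_SIGMA2 = {"study": 0.05, "species": 0.02, "phylogeny": 0.08, "unit": 0.10}


@dataclass(frozen=True)
class RbisSimConfig:
    """Two-group normal simulation for the corrected-vs-buggy d comparison.

    Defaults are the dark/light group parameters of the motivating dataset
    (dark 2.40 +- 0.80, light 2.25 +- 0.75) with 10 observations per group
    (the dataset's first-quartile group size; 70 is its maximum).
    """

    mean_dark: float = 2.40
    sd_dark: float = 0.80
    mean_light: float = 2.25
    sd_light: float = 0.75
    n_per_group: int = 10
    reps: int = 10_000
    seed: int = 42

    def __post_init__(self) -> None:
        if self.reps < 100:
            raise ValueError("need at least 100 replicates")
        if self.sd_dark <= 0 or self.sd_light <= 0:
            raise ValueError("group SDs must be positive")


def simulate_rbis_comparison(cfg: RbisSimConfig) -> dict[str, dict[str, float]]:
    """Replicate-level biserial correlations under both conversion variants.

    Returns ``{"fixed": {...}, "buggy": {...}}`` with mean, sd, min, max of
    the biserial values across replicates (plus the raw values).
    """
    rng = np.random.default_rng(cfg.seed)
    values = {"fixed": np.empty(cfg.reps), "buggy": np.empty(cfg.reps)}
    n = cfg.n_per_group
    for i in range(cfg.reps):
        dark = rng.normal(cfg.mean_dark, cfg.sd_dark, n)
        light = rng.normal(cfg.mean_light, cfg.sd_light, n)
        g = GroupSummary(
            mean_dark=float(dark.mean()), mean_light=float(light.mean()),
            sd_dark=float(dark.std(ddof=1)), sd_light=float(light.std(ddof=1)),
            n_dark=n, n_light=n,
        )
        for variant in ("fixed", "buggy"):
            r, _ = es.rbis_from_group_summary(g, variant=variant)
            values[variant][i] = r
    out = {}
    for variant, x in values.items():
        out[variant] = {
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)),
            "min": float(x.min()),
            "max": float(x.max()),
            "values": x,
        }
    return out


def simulate_tree(n_species: int, seed: int = 0, prefix: str = "sp") -> Phylogeny:
    """Random rooted binary topology by sequential random joins, Grafen lengths."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for i in range(n_species):
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(f"{prefix}{i + 1:03d}")
        nodes.append(node)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nd for idx, nd in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return grafen_lengths(Phylogeny(tree))


@dataclass(frozen=True)
class SyntheticConfig:
    """True parameters of a synthetic multilevel meta-analytic dataset.

    Defaults emulate the empirical dataset's shape: 74 studies on 54 species
    yielding roughly 170 effects (1-4 per study), group sizes between 10 and
    70 per group, a mixed diet of effect-size origins, and variance
    components at the study/species/phylogeny/unit levels.
    """

    n_studies: int = 74
    n_species: int = 54
    effects_per_study_range: tuple[int, int] = (1, 4)
    sigma2_true: dict = field(default_factory=lambda: dict(DEFAULT_SIGMA2))
    mu_true: float = 0.2
    origin_mixture: dict = field(default_factory=lambda: dict(DEFAULT_ORIGIN_MIXTURE))
    n_per_group_range: tuple[int, int] = (10, 70)
    tree_seed: int = 1
    data_seed: int = 2

    def __post_init__(self) -> None:
        probs = np.array(list(self.origin_mixture.values()), dtype=float)
        if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("origin mixture must sum to 1")
        if self.effects_per_study_range[0] > self.effects_per_study_range[1]:
            raise ValueError("empty effects-per-study range")
        if self.n_per_group_range[0] > self.n_per_group_range[1]:
            raise ValueError("empty group-size range")
        if self.n_studies < 1 or self.n_species < 2:
            raise ValueError("need at least 1 study and 2 species")
        if any(s < 0 for s in self.sigma2_true.values()):
            raise ValueError("variance components must be nonnegative")


def _delta_for_rho(rho: float, p: float) -> float:
    """Standardized mean difference whose point-biserial equals rho."""
    q = 1.0 - p
    return rho / math.sqrt(p * q * (1.0 - rho * rho))


def _chi2_from_table(table: np.ndarray) -> float:
    """Pearson chi-square of a 2x2 table (no continuity correction)."""
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / n
    return float(np.sum((table - expected) ** 2 / expected))


def simulate_meta_dataset(cfg: SyntheticConfig
                          ) -> tuple[pd.DataFrame, Phylogeny, dict]:
    """Draw a raw extraction table with known truth.

    Returns ``(table, tree, truth)``: the table is in the pipeline's input
    CSV dialect (one row per effect), the tree carries Grafen lengths, and
    the truth record holds the grand mean, the variance components, and the
    per-effect true correlations (pre- and post-clamp), plus the clamping
    count.
    """
    max_effects = cfg.n_studies * cfg.effects_per_study_range[1]
    if cfg.n_studies > max_effects:
        raise ValueError("infeasible configuration: more studies than possible effects")
    tree = simulate_tree(cfg.n_species, seed=cfg.tree_seed)
    corr = correlation_matrix(tree)
    species_labels = list(corr.species_order)
    rng = np.random.default_rng(cfg.data_seed)

    s2 = {name: float(cfg.sigma2_true.get(name, 0.0)) for name in
          ("study", "species", "phylogeny", "unit")}
    n_sp = len(species_labels)
    u_species = rng.normal(0.0, math.sqrt(s2["species"]), n_sp) if s2["species"] > 0 \
        else np.zeros(n_sp)
    if s2["phylogeny"] > 0:
        L = np.linalg.cholesky(corr.matrix + 1e-10 * np.eye(n_sp))
        u_phylo = math.sqrt(s2["phylogeny"]) * (L @ rng.standard_normal(n_sp))
    else:
        u_phylo = np.zeros(n_sp)

    # each species hosts at least one study when possible
    study_species = np.concatenate([
        rng.permutation(n_sp)[: min(cfg.n_studies, n_sp)],
        rng.integers(0, n_sp, max(cfg.n_studies - n_sp, 0)),
    ])
    u_study = rng.normal(0.0, math.sqrt(s2["study"]), cfg.n_studies) if s2["study"] > 0 \
        else np.zeros(cfg.n_studies)

    origins = list(cfg.origin_mixture.keys())
    probs = np.array([cfg.origin_mixture[o] for o in origins], dtype=float)

    rows: list[dict] = []
    rho_true: list[float] = []
    clamped = 0
    eid = 0
    for s in range(cfg.n_studies):
        sp_idx = int(study_species[s])
        n_effects = int(rng.integers(cfg.effects_per_study_range[0],
                                     cfg.effects_per_study_range[1] + 1))
        for _ in range(n_effects):
            eid += 1
            u_unit = rng.normal(0.0, math.sqrt(s2["unit"])) if s2["unit"] > 0 else 0.0
            rho_raw = cfg.mu_true + u_study[s] + u_species[sp_idx] + u_phylo[sp_idx] + u_unit
            rho = float(np.clip(rho_raw, -RHO_CLAMP, RHO_CLAMP))
            if rho != rho_raw:
                clamped += 1
            origin = origins[int(rng.choice(len(origins), p=probs))]
            row = _simulate_effect_row(rng, origin, rho, cfg)
            row.update({
                "effect_id": f"e{eid:04d}",
                "study_id": f"study{s + 1:03d}",
                "species": species_labels[sp_idx],
            })
            rows.append(row)
            rho_true.append(rho)

    table = pd.DataFrame(rows)[es.INPUT_COLUMNS]
    truth = {
        "mu": cfg.mu_true,
        "sigma2": s2,
        "rho_true": rho_true,
        "n_clamped": clamped,
        "k": len(rows),
        "n_studies": cfg.n_studies,
        "n_species": cfg.n_species,
    }
    return table, tree, truth


def _blank_row() -> dict:
    return {col: "" for col in es.INPUT_COLUMNS}


def _simulate_effect_row(rng: np.random.Generator, origin: Origin, rho: float,
                         cfg: SyntheticConfig) -> dict:
    """Raw summary statistics for one effect, consistent with its origin."""
    lo, hi = cfg.n_per_group_range
    n_group = int(rng.integers(lo, hi + 1))
    row = _blank_row()
    row["origin"] = origin.value
    row["scale_reversed"] = False

    if origin is Origin.PEARSON_R:
        n = 2 * n_group
        x = _bivariate_sample(rng, rho, n)
        r_obs = float(np.corrcoef(x[:, 0], x[:, 1])[0, 1])
        row.update(stat_value=r_obs, n_total=n, direction="")
        return row

    if origin is Origin.MEANS_SD_N:
        n_dark = n_group
        n_light = int(rng.integers(lo, hi + 1))
        n = n_dark + n_light
        x = _bivariate_sample(rng, rho, n)
        # dichotomize the latent trait so exactly n_dark fall in the dark group
        order = np.argsort(-x[:, 0])
        dark = np.zeros(n, dtype=bool)
        dark[order[:n_dark]] = True
        y = x[:, 1]
        row.update(
            mean_dark=float(y[dark].mean()), sd_dark=float(y[dark].std(ddof=1)),
            n_dark=n_dark,
            mean_light=float(y[~dark].mean()), sd_light=float(y[~dark].std(ddof=1)),
            n_light=n_light, n_total=n, direction="",
        )
        return row

    if origin in (Origin.T_VALUE, Origin.F_VALUE):
        n1 = n2 = n_group
        n = n1 + n2
        delta = _delta_for_rho(rho, n1 / n)
        g1 = rng.normal(delta, 1.0, n1)
        g2 = rng.normal(0.0, 1.0, n2)
        sp = math.sqrt(((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n - 2))
        t = (g1.mean() - g2.mean()) / (sp * math.sqrt(1 / n1 + 1 / n2))
        if origin is Origin.T_VALUE:
            row.update(stat_value=float(t), df2=n - 2, n_total=n,
                       n_dark=n1, n_light=n2, direction="")
        else:
            row.update(stat_value=float(t * t), df1=1, df2=n - 2, n_total=n,
                       n_dark=n1, n_light=n2,
                       direction="positive" if t >= 0 else "negative")
        return row

    # chi-square: 2x2 multinomial whose phi coefficient equals rho
    n = 2 * n_group
    p11 = p00 = (1.0 + rho) / 4.0
    p10 = p01 = (1.0 - rho) / 4.0
    for _ in range(100):
        counts = rng.multinomial(n, [p11, p10, p01, p00])
        tab = counts.reshape(2, 2)
        if tab.sum(axis=0).min() > 0 and tab.sum(axis=1).min() > 0:
            break
    chi2 = _chi2_from_table(tab)
    phi_sign = math.copysign(1.0, tab[0, 0] * tab[1, 1] - tab[0, 1] * tab[1, 0])
    row.update(stat_value=chi2, rows=2, cols=2, n_total=n,
               direction="positive" if phi_sign >= 0 else "negative")
    return row


def _bivariate_sample(rng: np.random.Generator, rho: float, n: int) -> np.ndarray:
    z = rng.standard_normal((n, 2))
    x = z[:, 0]
    y = rho * z[:, 0] + math.sqrt(1.0 - rho * rho) * z[:, 1]
    return np.column_stack([x, y])


def simulate_r_scale_dataset(cfg: SyntheticConfig, corr: PhyloCorrelation | None = None,
                             rho_within: float = 0.5) -> tuple[MetaDataset, dict]:
    """Fast path: effects drawn directly on the correlation scale.

    Skips raw-statistic generation and conversion; sampling errors are drawn
    from the block VCV implied by the known per-effect variances, so this is
    the generator of choice for estimator-level recovery and coverage runs.
    """
    if corr is None:
        corr = correlation_matrix(simulate_tree(cfg.n_species, seed=cfg.tree_seed))
    species_labels = list(corr.species_order)
    n_sp = len(species_labels)
    rng = np.random.default_rng(cfg.data_seed)
    s2 = {name: float(cfg.sigma2_true.get(name, 0.0)) for name in
          ("study", "species", "phylogeny", "unit")}

    u_species = rng.normal(0.0, math.sqrt(s2["species"]), n_sp)
    L = np.linalg.cholesky(corr.matrix + 1e-10 * np.eye(n_sp))
    u_phylo = math.sqrt(s2["phylogeny"]) * (L @ rng.standard_normal(n_sp))
    study_species = np.concatenate([
        rng.permutation(n_sp)[: min(cfg.n_studies, n_sp)],
        rng.integers(0, n_sp, max(cfg.n_studies - n_sp, 0)),
    ])
    u_study = rng.normal(0.0, math.sqrt(s2["study"]), cfg.n_studies)

    study_ids, species, mu_i, n_eff = [], [], [], []
    for s in range(cfg.n_studies):
        n_effects = int(rng.integers(cfg.effects_per_study_range[0],
                                     cfg.effects_per_study_range[1] + 1))
        sp_idx = int(study_species[s])
        for _ in range(n_effects):
            u_unit = rng.normal(0.0, math.sqrt(s2["unit"]))
            mu_i.append(float(np.clip(
                cfg.mu_true + u_study[s] + u_species[sp_idx] + u_phylo[sp_idx] + u_unit,
                -RHO_CLAMP, RHO_CLAMP)))
            study_ids.append(f"study{s + 1:03d}")
            species.append(species_labels[sp_idx])
            n_g = int(rng.integers(*cfg.n_per_group_range) + 1)
            n_eff.append(2 * n_g)
    k = len(mu_i)
    mu_i = np.array(mu_i)
    n_eff = np.array(n_eff, dtype=float)
    # known-variance assumption of the model: v depends on sample size only,
    # not on the realized random effects (the raw-statistic generator keeps
    # the realistic v(r) coupling instead)
    v = (1.0 - cfg.mu_true**2) ** 2 / (n_eff - 1)
    V = build_sampling_vcv(v, np.array(study_ids), rho=rho_within)
    e = np.linalg.cholesky(V + 1e-12 * np.eye(k)) @ rng.standard_normal(k)
    y = mu_i + e
    dataset = MetaDataset(
        y=y, v=v, study_ids=np.array(study_ids), species=np.array(species),
        n_eff=n_eff, sampling_vcv=V,
        moderators=pd.DataFrame({"effect_id": [f"e{i+1:04d}" for i in range(k)],
                                 "origin": ["pearson_r"] * k}),
        phylo_corr=corr, rho=rho_within,
    )
    truth = {"mu": cfg.mu_true, "sigma2": s2, "k": k, "rho_true": mu_i.tolist()}
    return dataset, truth


def apply_selection_bias(table: pd.DataFrame, n_threshold: int = 40,
                         variant: str = "fixed") -> pd.DataFrame:
    """Censor small, negative effects (a crude publication-selection mechanism).

    Rows whose converted correlation is negative and whose total sample size
    is below ``n_threshold`` are dropped, mimicking small nonsignificant or
    sign-discordant results staying unpublished.
    """
    converted = es.convert_table(table, variant=variant)
    n_total = pd.to_numeric(converted["n_total"])
    keep = ~((converted["r"] < 0) & (n_total < n_threshold))
    return table.loc[keep.to_numpy()].reset_index(drop=True)
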