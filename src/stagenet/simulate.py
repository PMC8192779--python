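"""Synthetic three-group expression cohorts with known planted structure.

The generator emulates a small staged-disease cohort: log2 expression for a
mix of lncRNAs and mRNAs across normal, early-stage and advanced-stage
samples.  Each gene g in sample j of stage c follows

    x_gj = mu_g + delta_{g,c} + beta * z_{m(g),j} * active(m(g), j) + eps_gj

with baseline ``mu_g ~ Normal(7, 1)``, residual noise
``eps ~ Normal(0, sigma^2)`` and, for module members, a shared latent
factor ``z`` drawn per sample that is switched on only in the module's
active stage(s).  Stage shifts ``delta_{g,c}`` encode the planted classes:

* ``pathogenic_up`` / ``pathogenic_down`` — +/- delta in both disease
  stages (consistent pathogenic pattern);
* ``progression_rebound`` — +delta in early, +delta/2 in advanced: up
  sharply at onset, partially back down with progression but still above
  normal (the rebound trajectory);
* ``marker`` — no mean shift, but loaded with coefficient ``-beta`` on the
  key lncRNA's module factor across disease samples, so markers
  anticorrelate with the key lncRNA within the disease cohort;
* ``module_member`` — shared-factor co-expression; members additionally
  carry the stage shift matching their module's activity window (disease-
  wide modules follow the pathogenic pattern, stage-specific modules the
  rebound pattern) so that modules land inside the differential-expression
  signatures that gate downstream network construction;
* ``null`` — baseline plus noise only.

Every module has one lncRNA driver and ``module_size - 1`` mRNA partners;
module activity cycles through disease-wide, early-only and advanced-only.
The driver of the first disease-wide module is the designated **key
lncRNA** used by the marker-correlation analysis.  A single integer seed is
expanded into independent substreams, so the same seed reproduces the
cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneSet, GeneSetCollection, StagenetError

MODULE_STAGES = ("all_ipf", "early", "advanced")

#: GroundTruth gene classes.
CLASSES = (
    "null",
    "pathogenic_up",
    "pathogenic_down",
    "progression_rebound",
    "marker",
    "module_member",
)

_CHROMS = [f"chr{i}" for i in range(1, 23)] + ["chrX"]


@dataclass(frozen=True)
class SimConfig:
    """Cohort-generator settings.

    Group sizes default to the study design the generator emulates
    (6 normal, 8 early-stage, 9 advanced-stage); ``delta`` is the planted
    log2 effect size, ``sigma`` the residual SD and ``beta`` the latent
    factor loading that controls within-module correlation
    (``beta^2 / (beta^2 + sigma^2)`` in the active stage).
    """

    n_normal: int = 6
    n_early: int = 8
    n_advanced: int = 9
    n_lncRNA: int = 60
    n_mRNA: int = 600
    frac_pathogenic: float = 0.05
    frac_progression: float = 0.03
    n_marker: int = 6
    delta: float = 2.0
    sigma: float = 0.5
    beta: float = 1.1
    n_modules: int = 6
    module_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_normal", "n_early", "n_advanced", "n_lncRNA",
                     "n_mRNA", "n_marker", "n_modules", "module_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for name in ("frac_pathogenic", "frac_progression"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return self.n_lncRNA + self.n_mRNA

    @property
    def n_samples(self) -> int:
        return self.n_normal + self.n_early + self.n_advanced


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort.

    Returns ``(expression, samples, annotation, truth)``.  ``truth`` is a
    DataFrame indexed by gene id with columns ``class``, ``module_id``,
    ``module_stage``, ``is_driver``, ``expected_signature``; its ``attrs``
    carry the key lncRNA id and a flag for undersized groups.
    """
    n_module_genes = cfg.n_modules * cfg.module_size
    if n_module_genes > cfg.n_genes:
        raise StagenetError("n_modules * module_size exceeds the gene count")
    if cfg.n_modules > cfg.n_lncRNA:
        raise StagenetError("need one lncRNA driver per module")
    if cfg.n_modules * (cfg.module_size - 1) + cfg.n_marker > cfg.n_mRNA:
        raise StagenetError("not enough mRNAs for module partners and markers")

    rng_assign, rng_means, rng_factors, rng_noise, rng_ann = _substreams(
        cfg.seed, 5
    )

    lnc_ids = [f"LNC{i:04d}" for i in range(cfg.n_lncRNA)]
    mrna_ids = [f"MRNA{i:04d}" for i in range(cfg.n_mRNA)]
    genes = lnc_ids + mrna_ids
    biotype = {g: "lncRNA" for g in lnc_ids}
    biotype.update({g: "mRNA" for g in mrna_ids})

    samples = pd.DataFrame(
        {
            "sample_id": (
                [f"N{j:02d}" for j in range(cfg.n_normal)]
                + [f"E{j:02d}" for j in range(cfg.n_early)]
                + [f"A{j:02d}" for j in range(cfg.n_advanced)]
            ),
            "stage": (
                ["normal"] * cfg.n_normal
                + ["early"] * cfg.n_early
                + ["advanced"] * cfg.n_advanced
            ),
        }
    )
    stage_of = samples["stage"].to_numpy()
    is_early = stage_of == "early"
    is_advanced = stage_of == "advanced"
    is_ipf = is_early | is_advanced

    # --- planted class assignment ------------------------------------------
    truth = pd.DataFrame(
        {
            "class": "null",
            "module_id": pd.array([pd.NA] * cfg.n_genes, dtype="string"),
            "module_stage": pd.array([pd.NA] * cfg.n_genes, dtype="string"),
            "is_driver": False,
            "expected_signature": "none",
        },
        index=pd.Index(genes, name="gene_id"),
    )

    lnc_pool = list(rng_assign.permutation(lnc_ids))
    mrna_pool = list(rng_assign.permutation(mrna_ids))

    drivers = [lnc_pool.pop() for _ in range(cfg.n_modules)]
    module_stage = [MODULE_STAGES[m % 3] for m in range(cfg.n_modules)]
    modules: dict[str, list[str]] = {}
    for m in range(cfg.n_modules):
        members = [drivers[m]] + [mrna_pool.pop() for _ in range(cfg.module_size - 1)]
        mid = f"M{m}"
        modules[mid] = members
        truth.loc[members, "class"] = "module_member"
        truth.loc[members, "module_id"] = mid
        truth.loc[members, "module_stage"] = module_stage[m]
        truth.loc[drivers[m], "is_driver"] = True
        truth.loc[members, "expected_signature"] = (
            "pathogenic" if module_stage[m] == "all_ipf" else "progression"
        )
    key_lnc = drivers[0] if cfg.n_modules else None

    markers = [mrna_pool.pop() for _ in range(cfg.n_marker)]
    truth.loc[markers, "class"] = "marker"

    free = lnc_pool + mrna_pool
    free = list(rng_assign.permutation(free))
    n_path = int(round(cfg.frac_pathogenic * cfg.n_genes))
    n_reb = int(round(cfg.frac_progression * cfg.n_genes))
    if n_path + n_reb > len(free):
        raise StagenetError("planted fractions exceed the unassigned gene pool")
    path_genes = [free.pop() for _ in range(n_path)]
    up = path_genes[: (n_path + 1) // 2]
    down = path_genes[(n_path + 1) // 2:]
    truth.loc[up, "class"] = "pathogenic_up"
    truth.loc[down, "class"] = "pathogenic_down"
    truth.loc[path_genes, "expected_signature"] = "pathogenic"
    reb_genes = [free.pop() for _ in range(n_reb)]
    truth.loc[reb_genes, "class"] = "progression_rebound"
    truth.loc[reb_genes, "expected_signature"] = "progression"

    # --- stage mean shifts --------------------------------------------------
    delta = pd.DataFrame(
        0.0, index=truth.index, columns=["normal", "early", "advanced"]
    )
    delta.loc[up, ["early", "advanced"]] = cfg.delta
    delta.loc[down, ["early", "advanced"]] = -cfg.delta
    delta.loc[reb_genes, "early"] = cfg.delta
    delta.loc[reb_genes, "advanced"] = cfg.delta / 2.0
    for mid, members in modules.items():
        stage = truth.at[members[0], "module_stage"]
        if stage == "all_ipf":
            delta.loc[members, ["early", "advanced"]] = cfg.delta
        else:
            delta.loc[members, "early"] = cfg.delta
            delta.loc[members, "advanced"] = cfg.delta / 2.0

    # --- assemble the matrix -------------------------------------------------
    mu = rng_means.normal(7.0, 1.0, size=cfg.n_genes)
    x = np.tile(mu[:, None], (1, cfg.n_samples))
    x += delta.to_numpy()[:, [("normal", "early", "advanced").index(s)
                              for s in stage_of]]

    z = rng_factors.standard_normal((cfg.n_modules, cfg.n_samples))
    active = {
        "all_ipf": is_ipf,
        "early": is_early,
        "advanced": is_advanced,
    }
    gene_pos = {g: i for i, g in enumerate(genes)}
    for m, (mid, members) in enumerate(modules.items()):
        mask = active[module_stage[m]]
        rows = [gene_pos[g] for g in members]
        x[np.ix_(rows, np.nonzero(mask)[0])] += cfg.beta * z[m, mask]
    if key_lnc is not None and markers:
        key_m = int(truth.at[key_lnc, "module_id"][1:])
        rows = [gene_pos[g] for g in markers]
        x[np.ix_(rows, np.nonzero(is_ipf)[0])] += -cfg.beta * z[key_m, is_ipf]

    x += rng_noise.normal(0.0, cfg.sigma, size=x.shape)

    em = pd.DataFrame(x, index=truth.index.copy(), columns=samples["sample_id"])
    em.columns.name = None

    # --- annotation -----------------------------------------------------------
    chrom = rng_ann.choice(_CHROMS, size=cfg.n_genes)
    start = rng_ann.integers(1, 100_000_000, size=cfg.n_genes)
    length = rng_ann.integers(500, 100_000, size=cfg.n_genes)
    annotation = pd.DataFrame(
        {
            "symbol": genes,
            "biotype": [biotype[g] for g in genes],
            "chrom": chrom,
            "start": start,
            "end": start + length,
        },
        index=truth.index.copy(),
    )

    small = min(cfg.n_normal, cfg.n_early, cfg.n_advanced) < 2
    truth.attrs["key_lncRNA"] = key_lnc
    truth.attrs["groups_undersized"] = bool(small)
    return em, samples, annotation, truth


def generate_gene_sets(
    truth: pd.DataFrame,
    cfg: SimConfig,
    n_fibrosis_sets: int = 20,
    n_pathway_sets: int = 15,
    frac_enriched: float = 0.25,
    set_size: int = 20,
    n_seeded: int = 10,
) -> GeneSetCollection:
    """Build gene-set collections with known planted enrichment.

    A fraction of the fibrosis-category sets is "enriched": seeded with
    ``n_seeded`` planted module mRNAs plus random fillers; the remainder
    (and the whole pathway-category collection) are uniform random draws
    from the gene universe.  Set names encode their construction
    (``FIBROSIS_ENRICHED_*`` vs ``FIBROSIS_RANDOM_*``) so the expected
    hypergeometric overlap is recoverable from the truth table.
    """
    universe = list(truth.index)
    if set_size > len(universe):
        raise StagenetError("set size exceeds the gene universe")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(6)[5])
    module_mrnas = [
        g for g in truth.index
        if truth.at[g, "class"] == "module_member" and not truth.at[g, "is_driver"]
    ]
    n_enriched = int(round(frac_enriched * n_fibrosis_sets))
    sets: list[GeneSet] = []
    for i in range(n_fibrosis_sets):
        if i < n_enriched and module_mrnas:
            seeded = list(
                rng.choice(module_mrnas, size=min(n_seeded, len(module_mrnas)),
                           replace=False)
            )
            fillers = [g for g in universe if g not in set(seeded)]
            picked = list(
                rng.choice(fillers, size=set_size - len(seeded), replace=False)
            )
            name = f"FIBROSIS_ENRICHED_{i}"
            members = frozenset(seeded + picked)
        else:
            name = f"FIBROSIS_RANDOM_{i}"
            members = frozenset(rng.choice(universe, size=set_size, replace=False))
        sets.append(GeneSet(name=name, category="fibrosis", members=members))
    for i in range(n_pathway_sets):
        members = frozenset(rng.choice(universe, size=set_size, replace=False))
        sets.append(GeneSet(name=f"PATHWAY_{i}", category="pathway",
                            members=members))
    return GeneSetCollection(sets=sets)
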