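"""Three-contrast differential expression and signature classification.

The cohort carries three sample groups (normal lung, early-stage disease,
advanced-stage disease) and every gene is tested in three pairwise
comparisons with a pooled-variance two-sample Student t-test:

* contrast 1 — early vs normal,
* contrast 2 — advanced vs normal,
* contrast 3 — advanced vs early.

Genes below the significance threshold (default ``alpha = 0.01``, no
multiple-testing correction) in a contrast are called differentially
expressed (DE) there.  Signatures are intersections of the per-contrast DE
sets:

* **pathogenic** — DE in contrasts 1 and 2 (disease of either stage differs
  from normal);
* **progression** — DE in contrasts 1 and 3 under the default
  ``methods`` rule, or contrasts 2 and 3 under the alternative ``results``
  rule (both rules are circulated in practice; the switch keeps them both
  available);
* **all_three** — DE in every contrast.

A gene shows the **rebound** pattern when it rises sharply from normal to
early stage, falls significantly from early to advanced, yet stays above the
normal level in advanced disease (the mirror-image trajectory is flagged as
a down-rebound).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import STAGES, StagenetError, stage_samples

logger = logging.getLogger(__name__)


class DegenerateTestError(StagenetError):
    pass


@dataclass(frozen=True)
class TestResult:
    """Outcome of one pooled-variance two-sample t-test."""

    t: float
    df: float
    p: float
    mean_diff: float
    direction: str  # up / down / flat, by the sign of mean_diff
    degenerate: bool = False


@dataclass(frozen=True)
class DEConfig:
    alpha: float = 0.01
    progression_rule: str = "methods"  # "methods" = c1&c3, "results" = c2&c3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.progression_rule not in ("methods", "results"):
            raise ValueError("progression_rule must be 'methods' or 'results'")


def _direction(mean_diff: float) -> str:
    if mean_diff > 0:
        return "up"
    if mean_diff < 0:
        return "down"
    return "flat"


def student_t(x, y) -> TestResult:
    """Pooled-variance two-sample Student t-test (two-sided).

    ``df = n_x + n_y - 2``; ``mean_diff = mean(x) - mean(y)``.  When the
    pooled variance vanishes the test degenerates: equal means give
    ``t = 0, p = 1``; unequal means give ``p = 0`` with the ``degenerate``
    flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    nx, ny = x.size, y.size
    df = nx + ny - 2
    mean_diff = float(x.mean() - y.mean())
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    if sp2 == 0.0:
        if mean_diff == 0.0:
            return TestResult(0.0, df, 1.0, 0.0, "flat", degenerate=True)
        t = np.inf if mean_diff > 0 else -np.inf
        return TestResult(float(t), df, 0.0, mean_diff, _direction(mean_diff),
                          degenerate=True)
    t = mean_diff / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), mean_diff,
                      _direction(mean_diff))


def _pooled_t_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pooled t over gene rows: a (genes x n_a) vs b (genes x n_b).

    Returns (t, p); genes with zero pooled variance follow the same
    degenerate convention as :func:`student_t`.
    """
    na, nb = a.shape[1], b.shape[1]
    df = na + nb - 2
    diff = a.mean(axis=1) - b.mean(axis=1)
    sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero = sp2 == 0.0
    if zero.any():
        t = t.copy()
        p = p.copy()
        flat = zero & (diff == 0.0)
        t[flat] = 0.0
        p[flat] = 1.0
        sep = zero & (diff != 0.0)
        t[sep] = np.where(diff[sep] > 0, np.inf, -np.inf)
        p[sep] = 0.0
    return t, p


def run_contrasts(em: pd.DataFrame, st: pd.DataFrame) -> pd.DataFrame:
    """Run the three stage contrasts for every gene.

    Returns a DataFrame indexed by gene with columns ``t{k}``, ``p{k}``,
    ``dir{k}``, ``diff{k}`` for k = 1..3 plus the three stage means
    (``mean_normal``, ``mean_early``, ``mean_advanced``).
    """
    groups = {}
    for stage in STAGES:
        ids = stage_samples(st, stage)
        if len(ids) < 2:
            raise StagenetError(
                f"stage {stage!r} has {len(ids)} samples; need >=2 for contrasts"
            )
        groups[stage] = em[ids].to_numpy(dtype=float)

    out = pd.DataFrame(index=em.index.copy())
    pairs = {
        1: ("early", "normal"),
        2: ("advanced", "normal"),
        3: ("advanced", "early"),
    }
    for k, (case, ref) in pairs.items():
        t, p = _pooled_t_matrix(groups[case], groups[ref])
        diff = groups[case].mean(axis=1) - groups[ref].mean(axis=1)
        out[f"t{k}"] = t
        out[f"p{k}"] = p
        out[f"diff{k}"] = diff
        out[f"dir{k}"] = np.where(diff > 0, "up", np.where(diff < 0, "down", "flat"))
    for stage in STAGES:
        out[f"mean_{stage}"] = groups[stage].mean(axis=1)
    return out


@dataclass
class SignatureSets:
    """DE sets per contrast and their intersections.

    ``rebound_labels`` maps each rebound gene to ``"up"`` or ``"down"``
    depending on the trajectory's direction.
    """

    deg1: set[str]
    deg2: set[str]
    deg3: set[str]
    pathogenic: set[str]
    progression: set[str]
    all_three: set[str]
    rebound: set[str] = field(default_factory=set)
    rebound_labels: dict[str, str] = field(default_factory=dict)
    direction_consistent: dict[str, bool] = field(default_factory=dict)
    biotype: dict[str, str] = field(default_factory=dict)
    progression_rule: str = "methods"

    def split_by_biotype(self, genes: set[str]) -> dict[str, int]:
        """Count lncRNA / mRNA / other members of a gene set."""
        counts = {"lncRNA": 0, "mRNA": 0, "other": 0}
        for g in genes:
            counts[self.biotype.get(g, "other")] += 1
        return counts


def classify_signatures(
    ct: pd.DataFrame,
    annotation: pd.DataFrame | None,
    cfg: DEConfig = DEConfig(),
) -> SignatureSets:
    """Derive the signature sets from a contrast table.

    ``deg_k`` collects genes with ``p_k < alpha``.  Pathogenic membership is
    ``deg1 & deg2`` with a per-gene flag recording whether the contrast-1 and
    contrast-2 effect directions agree (annotated, not enforced).  Progression
    membership follows ``cfg.progression_rule``.  Genes absent from the
    annotation are classified with biotype ``other`` and a warning.
    """
    alpha = cfg.alpha
    deg1 = set(ct.index[ct["p1"] < alpha])
    deg2 = set(ct.index[ct["p2"] < alpha])
    deg3 = set(ct.index[ct["p3"] < alpha])
    pathogenic = deg1 & deg2
    if cfg.progression_rule == "methods":
        progression = deg1 & deg3
    else:
        progression = deg2 & deg3
    all_three = deg1 & deg2 & deg3

    consistent = {
        g: bool(np.sign(ct.at[g, "diff1"]) == np.sign(ct.at[g, "diff2"]))
        for g in pathogenic
    }

    biotype: dict[str, str] = {}
    if annotation is not None:
        known = annotation["biotype"].to_dict()
        missing = [g for g in ct.index if g not in known]
        if missing:
            logger.warning(
                "%d genes missing from annotation; biotype set to 'other'",
                len(missing),
            )
        biotype = {g: known.get(g, "other") for g in ct.index}
    else:
        biotype = {g: "other" for g in ct.index}

    rebound_labels = detect_rebound(ct, alpha)
    return SignatureSets(
        deg1=deg1,
        deg2=deg2,
        deg3=deg3,
        pathogenic=pathogenic,
        progression=progression,
        all_three=all_three,
        rebound=set(rebound_labels),
        rebound_labels=rebound_labels,
        direction_consistent=consistent,
        biotype=biotype,
        progression_rule=cfg.progression_rule,
    )


def detect_rebound(ct: pd.DataFrame, alpha: float = 0.01) -> dict[str, str]:
    """Flag genes with the rebound trajectory.

    Up-rebound: significant rise from normal to early (contrast 1 up),
    significant fall from early to advanced (contrast 3 down), with the
    advanced mean still above the normal mean.  Down-rebound is the mirror
    image.  Returns ``{gene: "up" | "down"}``; an empty dict is a valid
    outcome.
    """
    up = (
        (ct["p1"] < alpha)
        & (ct["dir1"] == "up")
        & (ct["p3"] < alpha)
        & (ct["dir3"] == "down")
        & (ct["mean_advanced"] > ct["mean_normal"])
    )
    down = (
        (ct["p1"] < alpha)
        & (ct["dir1"] == "down")
        & (ct["p3"] < alpha)
        & (ct["dir3"] == "up")
        & (ct["mean_advanced"] < ct["mean_normal"])
    )
    labels: dict[str, str] = {g: "up" for g in ct.index[up]}
    labels.update({g: "down" for g in ct.index[down]})
    return labels


def contrast_table_tsv(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, sep="\t", index_label="gene_id")


def signature_tables(sig: SignatureSets) -> dict[str, pd.DataFrame]:
    """Render every signature set as a small table with a biotype column."""
    out = {}
    named = {
        "deg1": sig.deg1,
        "deg2": sig.deg2,
        "deg3": sig.deg3,
        "pathogenic": sig.pathogenic,
        "progression": sig.progression,
        "all_three": sig.all_three,
        "rebound": sig.rebound,
    }
    for name, genes in named.items():
        rows = []
        for g in sorted(genes):
            row = {"gene_id": g, "biotype": sig.biotype.get(g, "other")}
            if name == "pathogenic":
                row["direction_consistent"] = sig.direction_consistent.get(g, False)
            if name == "rebound":
                row["pattern"] = sig.rebound_labels.get(g, "")
            rows.append(row)
        out[name] = pd.DataFrame(rows)
    return out
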