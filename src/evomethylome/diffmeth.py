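"""Per-site differential methylation testing.

The reference statistic of the package: each cytosine's per-individual
fractional methylation is variance-stabilised with the arcsine link,

    y_i = arcsin( 2 * (m_i + delta) / (t_i + 2 * delta) - 1 ),

and regressed on the multifactor design (cell type, species, their
interaction, sex, three-level age class, bisulfite conversion rate) by
weighted least squares with the read totals t_i as weights. The Wald
statistic per term is coefficient / SE; its sign is the direction of the
methylation difference. Benjamini–Hochberg correction is applied per
(context, term) family.

The arcsine link makes the response variance approximately independent of the
methylation level, so a single per-site residual variance (estimated from the
weighted residuals, absorbing biological overdispersion across individuals)
calibrates the Wald t statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import CohortDataset

TERMS = ("cell_type", "species", "interaction")
DELTA = 0.5  # small-count stabiliser in the arcsine transform

AGE_LEVELS = ("young", "middle", "old")


class GroupError(ValueError):
    pass


# ---------------------------------------------------------------------------
# coverage filters
# ---------------------------------------------------------------------------

def _group_columns(sheet: pd.DataFrame, by: str) -> dict[str, np.ndarray]:
    groups = {}
    for level, idx in sheet.groupby(by).groups.items():
        cols = sheet.index.get_indexer(idx)
        if len(cols) == 0:
            raise GroupError(f"empty group {level!r}")
        groups[str(level)] = cols
    return groups


def filter_coverage_cg(dataset: CohortDataset, min_depth: int = 5,
                       min_frac: float = 0.8) -> np.ndarray:
    """CG depth filter: keep sites with >= min_depth coverage in at least
    ``min_frac`` of individuals within every species group and every
    cell-type group. Returns a boolean site mask."""
    keep = np.ones(dataset.n_sites, dtype=bool)
    for by in ("species", "cell_type"):
        for _, cols in _group_columns(dataset.sheet, by).items():
            ok = (dataset.coverage[:, cols] >= min_depth).mean(axis=1)
            keep &= ok >= min_frac
    return keep


def filter_sites_ch(dataset: CohortDataset, min_reads: int = 5,
                    max_bad_frac: float = 0.5) -> np.ndarray:
    """CH site filter: drop a site iff in at least one (species, cell type)
    group strictly more than ``max_bad_frac`` of individuals have fewer than
    ``min_reads`` reads."""
    labels = dataset.group_labels()
    keep = np.ones(dataset.n_sites, dtype=bool)
    for g in labels.unique():
        cols = np.flatnonzero((labels == g).to_numpy())
        if len(cols) == 0:
            raise GroupError(f"empty group {g!r}")
        bad = (dataset.coverage[:, cols] < min_reads).mean(axis=1)
        keep &= ~(bad > max_bad_frac)
    return keep


def select_and_downsample(sheet: pd.DataFrame, min_conversion: float = 0.995,
                          n_per_group: int = 11, seed: int = 0) -> list[str]:
    """High-conversion sample selection with matched group sizes.

    Samples below the conversion threshold (strict >) are ineligible; from the
    eligible pool exactly ``n_per_group`` samples per (species, cell_type)
    group are drawn uniformly without replacement, deterministically under
    ``seed``. Returns the selected sample ids in sheet order.
    """
    rng = np.random.default_rng(seed)
    eligible = sheet[sheet["conversion_rate"] > min_conversion]
    chosen: list[str] = []
    for (sp, ct), grp in sheet.groupby(["species", "cell_type"], sort=True):
        pool = eligible[(eligible["species"] == sp)
                        & (eligible["cell_type"] == ct)]["sample_id"].tolist()
        if len(pool) < n_per_group:
            raise GroupError(
                f"group ({sp}, {ct}): only {len(pool)} samples with "
                f"conversion > {min_conversion}, need {n_per_group}")
        if len(pool) == n_per_group:
            chosen.extend(pool)
        else:
            chosen.extend(rng.choice(pool, size=n_per_group, replace=False))
    order = {s: i for i, s in enumerate(sheet["sample_id"])}
    return sorted(chosen, key=order.get)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Dense design with named columns and term → column-index mapping."""

    X: np.ndarray = field(repr=False)
    columns: list[str]
    term_columns: dict[str, int]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


def build_design_matrix(sheet: pd.DataFrame,
                        terms: tuple[str, ...] = TERMS) -> DesignMatrix:
    """Treatment-coded design: intercept + requested terms + covariates.

    Reference levels: OLIG2 (cell type), the alphabetically first species
    present, female sex and the youngest age class. With two species each of
    ``species`` and ``interaction`` is a single column, so per-term Wald
    statistics are scalar.
    """
    n = len(sheet)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    term_columns: dict[str, int] = {}

    ct = (sheet["cell_type"] == "NeuN").to_numpy(float)
    species_levels = sorted(sheet["species"].unique())
    if "cell_type" in terms:
        if sheet["cell_type"].nunique() > 1:
            term_columns["cell_type"] = len(names)
            cols.append(ct)
            names.append("cell_type[NeuN]")
    if "species" in terms:
        if len(species_levels) > 2:
            raise GroupError("joint model supports two species per fit; "
                             "use pairwise_species_tests for 3-way data")
        if len(species_levels) == 2:
            sp = (sheet["species"] == species_levels[1]).to_numpy(float)
            term_columns["species"] = len(names)
            cols.append(sp)
            names.append(f"species[{species_levels[1]}]")
            if "interaction" in terms and sheet["cell_type"].nunique() > 1:
                term_columns["interaction"] = len(names)
                cols.append(sp * ct)
                names.append(f"species[{species_levels[1]}]:cell_type[NeuN]")

    if sheet["sex"].nunique() > 1:
        cols.append((sheet["sex"] == "M").to_numpy(float))
        names.append("sex[M]")
    present = [a for a in AGE_LEVELS if a in set(sheet["age_class"])]
    if not present:
        present = sorted(sheet["age_class"].unique())
    for level in present[1:]:
        cols.append((sheet["age_class"] == level).to_numpy(float))
        names.append(f"age_class[{level}]")
    cr = sheet["conversion_rate"].to_numpy(float)
    if np.ptp(cr) > 0:
        cols.append(cr - cr.mean())
        names.append("conversion_rate")

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise GroupError("design matrix is rank deficient")
    return DesignMatrix(X=X, columns=names, term_columns=term_columns)


# ---------------------------------------------------------------------------
# arcsine-link weighted least squares
# ---------------------------------------------------------------------------

def arcsine_transform(meth: np.ndarray, total: np.ndarray,
                      delta: float = DELTA) -> np.ndarray:
    """Variance-stabilising response; delta keeps 0/t and t/t off ±pi/2."""
    return np.arcsin(2.0 * (meth + delta) / (total + 2.0 * delta) - 1.0)


def fit_sites(dataset: CohortDataset, design: DesignMatrix,
              delta: float = DELTA) -> pd.DataFrame:
    """Vectorised per-site WLS fit; one row per site per requested term.

    Samples with zero coverage at a site drop out via zero weight. Sites
    whose weighted design loses full rank (an entire design cell missing)
    are flagged ``tested = False`` and carry NaN statistics.
    """
    X = design.X
    n_sites, n_samples = dataset.coverage.shape
    p = X.shape[1]
    w = dataset.coverage.astype(float)
    y = arcsine_transform(dataset.meth.astype(float), w, delta)
    y = np.where(w > 0, y, 0.0)

    xtwx = np.einsum("sn,np,nq->spq", w, X, X, optimize=True)
    xtwy = np.einsum("sn,np->sp", w * y, X, optimize=True)

    n_obs = (w > 0).sum(axis=1)
    df_resid = n_obs - p
    # rank check: a site is testable when every parameter is identifiable
    # from its non-zero-weight samples
    testable = df_resid > 0
    for s in np.flatnonzero(testable):
        # cheap necessary check first; full rank test only if suspicious
        if n_obs[s] < n_samples:
            if np.linalg.matrix_rank(X[w[s] > 0]) < p:
                testable[s] = False

    beta = np.full((n_sites, p), np.nan)
    se = np.full((n_sites, p), np.nan)
    ok = np.flatnonzero(testable)
    if len(ok):
        xtwx_ok = xtwx[ok]
        try:
            inv = np.linalg.inv(xtwx_ok)
        except np.linalg.LinAlgError:  # fall back site by site
            inv = np.stack([np.linalg.pinv(m) for m in xtwx_ok])
        b = np.einsum("spq,sq->sp", inv, xtwy[ok])
        resid = y[ok] - b @ X.T
        rss = np.einsum("sn,sn->s", w[ok] * resid, resid)
        sigma2 = rss / np.maximum(df_resid[ok], 1)
        beta[ok] = b
        se[ok] = np.sqrt(np.maximum(sigma2[:, None], 0)
                         * np.einsum("spp->sp", inv))

    rows = []
    gm = dataset.group_means()
    for term, j in design.term_columns.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            wald = beta[:, j] / se[:, j]
        pval = 2.0 * stats.t.sf(np.abs(wald), np.maximum(df_resid, 1))
        rows.append(pd.DataFrame({
            "chrom": dataset.sites["chrom"],
            "pos": dataset.sites["pos"],
            "strand": dataset.sites["strand"],
            "context": dataset.sites["context"],
            "term": term,
            "coef": beta[:, j],
            "se": se[:, j],
            "stat": wald,
            "p": pval,
            "tested": testable & np.isfinite(wald),
        }))
    result = pd.concat(rows, ignore_index=True)
    result.loc[~result["tested"], ["coef", "se", "stat", "p"]] = np.nan
    # per-group plain means travel with the site results for cutoff filters
    for g in gm.columns:
        result[f"mean_{g}"] = np.tile(gm[g].to_numpy(),
                                      len(design.term_columns))
    return result


def fit_site_model(dataset: CohortDataset,
                   terms: tuple[str, ...] = TERMS,
                   delta: float = DELTA,
                   q_by_term: bool = True) -> pd.DataFrame:
    """Multifactor fit plus per-term BH correction across tested sites."""
    design = build_design_matrix(dataset.sheet, terms)
    res = fit_sites(dataset, design, delta)
    res["q"] = np.nan
    fam = ["context", "term"] if q_by_term else ["context"]
    for _, idx in res[res["tested"]].groupby(fam).groups.items():
        res.loc[idx, "q"] = adjust_fdr(res.loc[idx, "p"].to_numpy())
    return res


def pairwise_species_tests(dataset: CohortDataset, pair: tuple[str, str],
                           cell_type: str | None = None,
                           delta: float = DELTA) -> pd.DataFrame:
    """Two-species comparison with species as the term of interest.

    Same machinery as :func:`fit_site_model`, restricted to the two species
    (and optionally one cell type), adjusting for sex, age class and
    conversion rate. The statistic's sign follows the second species minus
    the first in ``sorted(pair)`` on the arcsine scale; a convenience column
    ``diff`` carries mean(pair[0]) − mean(pair[1]) per cell type pooled.
    """
    sheet = dataset.sheet
    keep = sheet["species"].isin(pair)
    if cell_type is not None:
        keep &= sheet["cell_type"] == cell_type
    sub = dataset.subset_samples(sheet.loc[keep, "sample_id"])
    terms = ("species",) if cell_type is not None else ("cell_type", "species")
    res = fit_site_model(sub, terms=terms, delta=delta)
    res = res[res["term"] == "species"].reset_index(drop=True)
    gm = sub.group_means(by=("species",))
    a, b = pair
    res[f"mean_{a}"] = gm[a].to_numpy()
    res[f"mean_{b}"] = gm[b].to_numpy()
    res["diff"] = (gm[a] - gm[b]).to_numpy()
    res["pair"] = f"{a}_vs_{b}"
    return res


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values outside [0, 1]")
    if p.size == 0:
        return p.copy()
    q = np.full(p.shape, np.nan)
    m = np.isfinite(p)
    if m.any():
        q[m] = multipletests(p[m], method="fdr_bh")[1]
    return q
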