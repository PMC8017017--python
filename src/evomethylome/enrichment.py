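"""GC-matched permutation enrichment, specificity classification, matching.

Feature-overlap enrichment of a query interval set (e.g. human-specific
hypomethylated DMRs vs non-coding human accelerated regions) is assessed
against control region sets sampled to match each query region's length,
G+C fraction (±0.02) and CpG count (±10%), never overlapping the query set.
Fold enrichment is observed / mean(control) overlap counts; the empirical
p-value carries the +1 correction so it can never be exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class MatchingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# composition lookups (prefix sums over a fixed-step track)
# ---------------------------------------------------------------------------

class CompositionIndex:
    """Per-chromosome prefix sums of GC density and CG-site density.

    ``track``: frame [chrom, start, end, gc_frac, cg_count] with fixed-step
    disjoint windows. Region GC is the length-weighted window mean; region
    CG count is the (fractional) sum of per-window densities.
    """

    def __init__(self, track: pd.DataFrame):
        self.chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
        for chrom, grp in track.groupby("chrom"):
            grp = grp.sort_values("start")
            edges = np.append(grp["start"].to_numpy(), grp["end"].iloc[-1])
            widths = np.diff(edges).astype(float)
            gc_cum = np.concatenate([[0.0],
                                     np.cumsum(grp["gc_frac"].to_numpy() * widths)])
            cg_cum = np.concatenate([[0.0],
                                     np.cumsum(grp["cg_count"].to_numpy(float))])
            cg_dens = grp["cg_count"].to_numpy(float) / widths
            self.chroms[str(chrom)] = (edges, gc_cum,
                                       np.concatenate([[0.0],
                                                       np.cumsum(cg_dens * widths)]),
                                       int(edges[-1]))

    def size(self, chrom: str) -> int:
        return self.chroms[chrom][3]

    def _interp(self, cum: np.ndarray, edges: np.ndarray, x: float) -> float:
        i = np.clip(np.searchsorted(edges, x, side="right") - 1, 0,
                    len(edges) - 2)
        frac = (x - edges[i]) / (edges[i + 1] - edges[i])
        return float(cum[i] + frac * (cum[i + 1] - cum[i]))

    def gc_fraction(self, chrom: str, start: int, end: int) -> float:
        edges, gc_cum, _, _ = self.chroms[chrom]
        return (self._interp(gc_cum, edges, end)
                - self._interp(gc_cum, edges, start)) / (end - start)

    def cg_count(self, chrom: str, start: int, end: int) -> float:
        edges, _, cg_cum, _ = self.chroms[chrom]
        return (self._interp(cg_cum, edges, end)
                - self._interp(cg_cum, edges, start))


# ---------------------------------------------------------------------------
# matched control sampling
# ---------------------------------------------------------------------------

def _overlaps(starts: np.ndarray, ends: np.ndarray, s: int, e: int) -> bool:
    return bool(((starts < e) & (ends > s)).any())


def sample_matched_controls(query: pd.DataFrame, track: pd.DataFrame,
                            n_sets: int = 100, seed: int = 0,
                            gc_tol: float = 0.02, cg_rel_tol: float = 0.10,
                            max_attempts: int = 2000) -> list[pd.DataFrame]:
    """Draw ``n_sets`` control sets, one same-length GC/CG-matched region per
    query region, none overlapping the query set; deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    index = CompositionIndex(track)
    chroms = list(index.chroms)
    if query.empty:
        return [pd.DataFrame(columns=["chrom", "start", "end"])
                for _ in range(n_sets)]
    qstats = []
    for r in query.itertuples():
        qstats.append((r.chrom, int(r.start), int(r.end),
                       index.gc_fraction(r.chrom, r.start, r.end),
                       index.cg_count(r.chrom, r.start, r.end)))
    q_by_chrom = {c: (query.loc[query["chrom"] == c, "start"].to_numpy(),
                      query.loc[query["chrom"] == c, "end"].to_numpy())
                  for c in set(query["chrom"])}

    sets = []
    failures: list[str] = []
    for _ in range(n_sets):
        rows = []
        for chrom, qs, qe, qgc, qcg in qstats:
            length = qe - qs
            placed = False
            for _ in range(max_attempts):
                c = chroms[rng.integers(len(chroms))]
                limit = index.size(c) - length
                if limit <= 0:
                    continue
                s = int(rng.integers(0, limit))
                e = s + length
                if c in q_by_chrom and _overlaps(*q_by_chrom[c], s, e):
                    continue
                if abs(index.gc_fraction(c, s, e) - qgc) > gc_tol:
                    continue
                cg = index.cg_count(c, s, e)
                if abs(cg - qcg) > cg_rel_tol * max(qcg, 1.0):
                    continue
                rows.append({"chrom": c, "start": s, "end": e})
                placed = True
                break
            if not placed:
                failures.append(f"{chrom}:{qs}-{qe}")
        if failures:
            raise MatchingError("could not match control regions for: "
                                + ", ".join(sorted(set(failures))))
        sets.append(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    return sets


# ---------------------------------------------------------------------------
# permutation enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    query_label: str
    feature_label: str
    observed: int
    control_counts: np.ndarray = field(repr=False)
    fold_enrichment: float = 0.0
    empirical_p: float = 1.0


def count_overlapping_regions(query: pd.DataFrame,
                              feature: pd.DataFrame) -> int:
    """Number of query regions intersecting >= 1 feature interval (>= 1 bp)."""
    n = 0
    for chrom, grp in query.groupby("chrom"):
        f = feature[feature["chrom"] == chrom]
        if f.empty:
            continue
        fs, fe = f["start"].to_numpy(), f["end"].to_numpy()
        for r in grp.itertuples():
            if ((fs < r.end) & (fe > r.start)).any():
                n += 1
    return n


def permutation_enrichment(query: pd.DataFrame, feature: pd.DataFrame,
                           controls: list[pd.DataFrame],
                           query_label: str = "query",
                           feature_label: str = "feature") -> EnrichmentResult:
    """Fold enrichment = observed / mean(control overlaps);
    empirical p = (1 + #{controls >= observed}) / (n_controls + 1)."""
    if not controls:
        raise ValueError("need at least one control set")
    observed = count_overlapping_regions(query, feature)
    ctrl = np.array([count_overlapping_regions(c, feature) for c in controls])
    mean_ctrl = ctrl.mean()
    fold = observed / mean_ctrl if mean_ctrl > 0 else (
        np.inf if observed > 0 else 0.0)
    p = (1 + int((ctrl >= observed).sum())) / (len(ctrl) + 1)
    return EnrichmentResult(query_label, feature_label, observed, ctrl,
                            float(fold), float(p))


def classify_specificity(freq_a: pd.Series, freq_b: pd.Series,
                         hi: float = 0.95, lo: float = 0.05) -> pd.Series:
    """Per-feature specificity over repeated enrichment runs.

    ``freq_a``/``freq_b``: fraction of runs in which the feature was enriched
    in class A / class B (same index). A-specific iff freq_A > hi and
    freq_B < lo (strict); B-specific mirrored; else neither.
    """
    if not freq_a.index.equals(freq_b.index):
        raise ValueError("feature indexes differ")
    out = pd.Series("neither", index=freq_a.index)
    out[(freq_a > hi) & (freq_b < lo)] = "A-specific"
    out[(freq_b > hi) & (freq_a < lo)] = "B-specific"
    return out


def specificity_from_runs(runs_a: pd.DataFrame, runs_b: pd.DataFrame,
                          hi: float = 0.95, lo: float = 0.05) -> pd.Series:
    """Boolean features × runs matrices → specificity labels."""
    if runs_a.shape[1] != runs_b.shape[1]:
        raise ValueError("run counts differ")
    return classify_specificity(runs_a.mean(axis=1), runs_b.mean(axis=1),
                                hi, lo)


# ---------------------------------------------------------------------------
# count/length-matched down-sampling
# ---------------------------------------------------------------------------

def downsample_to_match(large: pd.DataFrame, reference: pd.DataFrame,
                        n_reps: int = 100, seed: int = 0,
                        n_bins: int = 10) -> list[pd.DataFrame]:
    """Repeatedly subsample ``large`` to the reference's size and length
    distribution by quantile-bin matching; deterministic under seed."""
    if len(large) < len(reference):
        raise ValueError("large set smaller than reference")
    rng = np.random.default_rng(seed)
    ref_len = (reference["end"] - reference["start"]).to_numpy()
    big_len = (large["end"] - large["start"]).to_numpy()
    n_bins = min(n_bins, max(1, len(reference)))
    edges = np.quantile(ref_len, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    ref_bin = np.digitize(ref_len, edges[1:-1])
    big_bin = np.digitize(big_len, edges[1:-1])
    need = np.bincount(ref_bin, minlength=n_bins)
    pools = [np.flatnonzero(big_bin == b) for b in range(n_bins)]
    for b in range(n_bins):
        if need[b] > len(pools[b]):
            raise MatchingError(
                f"length bin {b} needs {need[b]} regions, large set has "
                f"{len(pools[b])}")
    reps = []
    for _ in range(n_reps):
        idx = np.concatenate([
            rng.choice(pools[b], size=need[b], replace=False)
            for b in range(n_bins) if need[b] > 0])
        reps.append(large.iloc[np.sort(idx)].reset_index(drop=True))
    return reps
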