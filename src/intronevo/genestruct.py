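"""Exon-intron gene structure: extant exons, reshaping classes, position tests.

Coordinates are CDS-based: intron sites sit at 0-based nucleotide offsets
with half-open exon intervals, so the extant exons of a gene always tile
its CDS exactly.  Ordinal intron indices are 1-based from the 5' end.

Reshaping classes follow the called gain/loss history on the root-to-leaf
path of a species:

* an extant exon containing exactly k (1 or 2) called-loss sites and
  bounded by no called-gain site is a fusion of k+1 ancestral exons
  ("2-into-1", "3-into-1");
* a maximal run of k (1 or 2) consecutive called-gain sites splits one
  ancestral exon into k+1 extant pieces, each labelled "1-into-2" or
  "1-into-3";
* exons with both gain boundaries and internal losses, or with more than
  two events, are "excluded";
* everything with no called event at its boundaries or interior is
  "control".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IntronSiteInfo",
    "GeneModel",
    "GeneStructure",
    "ExonRecord",
    "extant_exons",
    "classify_reshaped",
    "length_comparison",
    "positional_profile",
    "positional_heterogeneity_test",
    "distance_to_start_test",
    "interval_overlap_bootstrap",
    "read_bed",
    "write_bed",
]

HISTORY_LABELS = ("gain", "loss", "presence")


@dataclass
class IntronSiteInfo:
    """One intron site within a gene, for one species."""

    site_id: str
    ordinal: int      # 1-based from the 5' end
    offset: int       # 0-based CDS nucleotide offset
    present: bool
    label: str = "uncalled"  # gain | loss | presence | uncalled


@dataclass
class GeneModel:
    """Ancestral view of a gene: ordered sites between exon segments."""

    gene_id: str
    site_ids: list[str]
    exon_lengths: np.ndarray  # k+1 ancestral segment lengths, nt

    @property
    def cds_length(self) -> int:
        return int(np.sum(self.exon_lengths))

    @property
    def offsets(self) -> np.ndarray:
        """CDS offset of each site (cumulative segment sums)."""
        return np.cumsum(self.exon_lengths)[:-1]


@dataclass
class GeneStructure:
    """Extant structure of one gene in one species."""

    gene_id: str
    species: str
    cds_length: int
    sites: list[IntronSiteInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        offsets = [s.offset for s in self.sites]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("site offsets must be strictly increasing")
        if any(not 0 < o < self.cds_length for o in offsets):
            raise ValueError("site offsets must lie strictly inside the CDS")

    @property
    def present_sites(self) -> list[IntronSiteInfo]:
        return [s for s in self.sites if s.present]


@dataclass
class ExonRecord:
    """One extant exon (half-open CDS interval) with its reshaping class."""

    gene_id: str
    species: str
    start: int
    end: int
    cls: str = "control"  # 1-into-2 | 1-into-3 | 2-into-1 | 3-into-1 | control | excluded

    @property
    def length(self) -> int:
        return self.end - self.start


def extant_exons(gene: GeneStructure) -> list[ExonRecord]:
    """Maximal CDS segments between consecutive extant-present sites."""
    bounds = [0] + [s.offset for s in gene.present_sites] + [gene.cds_length]
    return [
        ExonRecord(gene.gene_id, gene.species, a, b)
        for a, b in zip(bounds, bounds[1:])
    ]


def classify_reshaped(gene: GeneStructure) -> list[ExonRecord]:
    """Assign reshaping classes to the extant exons of one gene."""
    present = gene.present_sites
    exons = extant_exons(gene)

    # interior absent sites of each exon, and the boundary sites
    absent = [s for s in gene.sites if not s.present]
    interior: list[list[IntronSiteInfo]] = [[] for _ in exons]
    for s in absent:
        for j, e in enumerate(exons):
            if e.start < s.offset < e.end:
                interior[j].append(s)
                break
    left_bound = [None] + present      # boundary site left of exon j
    right_bound = present + [None]     # boundary site right of exon j

    n_internal_loss = [sum(s.label == "loss" for s in ins) for ins in interior]
    gain_left = [b is not None and b.label == "gain" for b in left_bound]
    gain_right = [b is not None and b.label == "gain" for b in right_bound]

    # maximal runs of consecutive called-gain boundary sites
    runs: list[tuple[int, int]] = []  # (first present-site index, run length)
    i = 0
    while i < len(present):
        if present[i].label == "gain":
            j = i
            while j + 1 < len(present) and present[j + 1].label == "gain":
                j += 1
            runs.append((i, j - i + 1))
            i = j + 1
        else:
            i += 1

    for j, e in enumerate(exons):
        has_gain = gain_left[j] or gain_right[j]
        k_loss = n_internal_loss[j]
        if has_gain and k_loss:
            e.cls = "excluded"
        elif k_loss:
            e.cls = f"{k_loss + 1}-into-1" if k_loss <= 2 else "excluded"
        elif has_gain:
            e.cls = "excluded"  # refined below from the run length
        else:
            e.cls = "control"

    for first, k in runs:
        # exons touched by a run of k gains: indices first .. first+k
        members = range(first, first + k + 1)
        if k > 2 or any(n_internal_loss[j] for j in members):
            continue  # stays excluded
        for j in members:
            exons[j].cls = f"1-into-{k + 1}"
    return exons


def length_comparison(exons: list[ExonRecord]):
    """Per-class length statistics and pairwise Welch t-tests.

    Returns (stats_frame, tests_frame).  Classes with fewer than two exons
    are reported in the statistics but excluded from the tests.
    """
    by_cls: dict[str, np.ndarray] = {}
    for e in exons:
        by_cls.setdefault(e.cls, []).append(e.length)
    by_cls = {c: np.asarray(v, dtype=float) for c, v in by_cls.items()}
    stats_rows = [
        {"class": c, "n": len(v), "median": float(np.median(v)),
         "mean": float(np.mean(v))}
        for c, v in sorted(by_cls.items())
    ]
    testable = {c: v for c, v in by_cls.items() if len(v) >= 2}
    test_rows = []
    names = sorted(testable)
    for a_i, a in enumerate(names):
        for b in names[a_i + 1:]:
            x, y = testable[a], testable[b]
            if np.var(x) == 0 and np.var(y) == 0:
                t, p = (0.0, 1.0) if np.mean(x) == np.mean(y) else (np.inf, 0.0)
            else:
                t, p = stats.ttest_ind(x, y, equal_var=False)
            test_rows.append({"class_a": a, "class_b": b,
                              "t": float(t), "p": float(p)})
    return pd.DataFrame(stats_rows), pd.DataFrame(test_rows)


def positional_profile(genes: list[GeneStructure]) -> dict:
    """Positions of gain/loss/presence sites along the gene body.

    Returns normalized positions (offset / CDS length) per history label
    and 3x3 ordinal count tables for the first and last three intron
    positions of each gene.
    """
    normalized: dict[str, list[float]] = {lab: [] for lab in HISTORY_LABELS}
    c5 = pd.DataFrame(0, index=list(HISTORY_LABELS), columns=[1, 2, 3])
    c3 = pd.DataFrame(0, index=list(HISTORY_LABELS), columns=[1, 2, 3])
    for g in genes:
        if g.cds_length <= 0:
            raise ValueError("CDS length must be positive")
        n = len(g.sites)
        for s in g.sites:
            if s.label not in HISTORY_LABELS:
                continue
            normalized[s.label].append(s.offset / g.cds_length)
            from_5p = s.ordinal
            from_3p = n - s.ordinal + 1
            if from_5p <= 3:
                c5.loc[s.label, from_5p] += 1
            if from_3p <= 3:
                c3.loc[s.label, from_3p] += 1
    return {
        "normalized": {lab: np.asarray(v) for lab, v in normalized.items()},
        "ordinal_5p": c5,
        "ordinal_3p": c3,
    }


def positional_heterogeneity_test(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise chi-square homogeneity tests between history labels.

    ``counts`` is a labels x positions table of nonnegative integers.
    Each pair of rows forms a 2 x m contingency table tested without
    continuity correction; labels whose row sums to zero are excluded and
    reported with NaN statistics.
    """
    counts = counts.astype(float)
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    rows = []
    labels = list(counts.index)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            sub = counts.loc[[a, b]]
            if (sub.sum(axis=1) == 0).any():
                rows.append({"label_a": a, "label_b": b,
                             "chi2": np.nan, "p": np.nan, "excluded": True})
                continue
            keep = sub.sum(axis=0) > 0  # drop all-zero columns
            chi2, p, _, _ = stats.chi2_contingency(
                sub.loc[:, keep].to_numpy(), correction=False
            )
            rows.append({"label_a": a, "label_b": b,
                         "chi2": float(chi2), "p": float(p), "excluded": False})
    return pd.DataFrame(rows)


def distance_to_start_test(
    genes: list[GeneStructure], n_null: int = 10, seed: int = 0
) -> dict:
    """Are first introns closer to the start codon than uniform placement?

    Observed sample: CDS offset of the first extant intron of every
    intron-containing gene.  Null sample: ``n_null`` offsets per gene
    drawn uniformly within its CDS.  Two-sample Kolmogorov-Smirnov test.
    """
    rng = np.random.default_rng(seed)
    observed = []
    null: list[int] = []
    for g in genes:
        ps = g.present_sites
        if not ps:
            continue
        observed.append(ps[0].offset)
        null.extend(rng.integers(1, g.cds_length, size=n_null).tolist())
    if not observed:
        raise ValueError("no intron-containing gene")
    ks = stats.ks_2samp(observed, null)
    return {"statistic": float(ks.statistic), "p": float(ks.pvalue),
            "n_observed": len(observed), "n_null": len(null)}


# -- interval overlap (repeat-enrichment style statistic) ------------------

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read a 3- to 6-column BED file (0-based half-open intervals)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def _merged(intervals: np.ndarray) -> np.ndarray:
    """Merge sorted (start, end) rows into disjoint intervals."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    order = np.argsort(intervals[:, 0], kind="stable")
    ivs = intervals[order]
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out)


def _covered_bases(features: np.ndarray, mask: np.ndarray) -> int:
    """Bases of ``features`` covered by merged ``mask`` (same chrom)."""
    mask = _merged(mask)
    total = 0
    for s, e in features:
        if len(mask) == 0:
            break
        lo = np.minimum(np.maximum(mask[:, 0], s), e)
        hi = np.minimum(mask[:, 1], e)
        total += int(np.maximum(hi - lo, 0).sum())
    return total


def interval_overlap_bootstrap(
    features: pd.DataFrame,
    mask: pd.DataFrame,
    seq_lengths: dict[str, int],
    B: int = 1000,
    seed: int = 0,
) -> dict:
    """Percent of feature bases covered by a mask, with a placement bootstrap.

    The point estimate is the percentage of feature bases overlapped by
    the mask intervals.  Each bootstrap replicate redraws a length-matched
    feature set (same number of intervals, same lengths, same chromosome,
    uniform random placement) and recomputes the percentage; the returned
    distribution quantifies what the overlap would look like for features
    with no positional preference.
    """
    for df, what in ((features, "feature"), (mask, "mask")):
        arr = df[["start", "end"]].to_numpy()
        if (arr[:, 1] <= arr[:, 0]).any():
            raise ValueError(f"malformed {what} interval (end <= start)")
        for chrom, grp in df.groupby("chrom"):
            if chrom not in seq_lengths:
                raise ValueError(f"unknown sequence {chrom!r}")
            if (grp["end"] > seq_lengths[chrom]).any():
                raise ValueError(f"{what} interval beyond end of {chrom!r}")

    mask_by_chrom = {
        chrom: grp[["start", "end"]].to_numpy()
        for chrom, grp in mask.groupby("chrom")
    }

    def percent(feat_by_chrom: dict[str, np.ndarray]) -> float:
        covered = 0
        total = 0
        for chrom, ivs in feat_by_chrom.items():
            total += int((ivs[:, 1] - ivs[:, 0]).sum())
            covered += _covered_bases(
                ivs, mask_by_chrom.get(chrom, np.empty((0, 2), dtype=int))
            )
        return 100.0 * covered / total if total else 0.0

    feat_by_chrom = {
        chrom: grp[["start", "end"]].to_numpy()
        for chrom, grp in features.groupby("chrom")
    }
    point = percent(feat_by_chrom)

    rng = np.random.default_rng(seed)
    dist = np.empty(B)
    for b in range(B):
        resampled = {}
        for chrom, ivs in feat_by_chrom.items():
            lengths = ivs[:, 1] - ivs[:, 0]
            starts = rng.integers(0, seq_lengths[chrom] - lengths + 1)
            resampled[chrom] = np.column_stack([starts, starts + lengths])
        dist[b] = percent(resampled)
    return {
        "percent": point,
        "bootstrap": dist,
        "bootstrap_median": float(np.median(dist)),
    }
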