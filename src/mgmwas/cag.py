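"""Co-abundance gene groups (CAGs) by canopy clustering.

Gene families whose abundances co-vary across samples are presumed to
originate from one genome. Canopy clustering grows groups greedily: a seed
profile is drawn from the unassigned pool, every pool profile correlating
above ``t_gather`` with the canopy centroid is gathered, the centroid is
recomputed as the per-sample median of members, and gathering repeats until
membership stabilises. Canopies whose centroids correlate above ``t_merge``
are merged, and canopies below ``min_size`` are dropped.

A CAG is annotated to a species when at least 80% of its member gene
families carry that species' stratification tag (boundary inclusive),
otherwise it stays "unclassified". CAG-level enrichment reuses the Wilcoxon
+ BH machinery on centroid profiles, and the correlation network keeps an
edge only when the centroid Pearson r exceeds ``pos_threshold`` (default
0.5) or falls below ``neg_threshold`` (default -0.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import diffabund
from .exceptions import DataError
from .profile_io import AbundanceTable, SampleMetadata, parse_stratification

#: member fraction required to assign a species label to a CAG (inclusive)
ANNOTATION_FRACTION = 0.8


@dataclass
class CAG:
    """A co-abundance gene group: members, centroid profile and annotation."""

    id: str
    members: list[str]
    centroid: pd.Series  # per-sample median profile
    species: str = "unclassified"
    enriched: str | None = None
    p: float | None = None
    q: float | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def _pearson_to_centroid(x: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Pearson r of each row of x against the centroid (NaN-safe: 0 variance -> NaN)."""
    xc = x - x.mean(axis=1, keepdims=True)
    cc = centroid - centroid.mean()
    xs = np.sqrt((xc**2).sum(axis=1))
    cs = np.sqrt((cc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ cc) / (xs * cs)
    return r


def canopy_cluster(
    profiles: AbundanceTable,
    t_gather: float = 0.9,
    t_merge: float = 0.97,
    min_size: int = 3,
    max_iter: int = 100,
    seed: int = 0,
) -> list[CAG]:
    """Cluster gene-family profiles into CAGs by correlation canopies.

    Seed profiles are drawn in a seeded random order; gathering uses strict
    ``r > t_gather`` against the (median) centroid. The result is a partition:
    gathered members leave the pool, so no gene family joins two canopies.
    """
    if profiles.n_samples < 2:
        raise ValueError("canopy clustering needs at least two samples")
    if t_merge < t_gather:
        raise ValueError("t_merge must be >= t_gather")
    features = list(profiles.features)
    x = profiles.data.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(features))
    unassigned = np.ones(len(features), dtype=bool)

    canopies: list[np.ndarray] = []  # arrays of feature indices
    centroids: list[np.ndarray] = []
    for idx in order:
        if not unassigned[idx]:
            continue
        members = np.array([idx])
        centroid = x[idx].astype(float)
        for _ in range(max_iter):
            r = _pearson_to_centroid(x, centroid)
            cand = np.nonzero(unassigned & (r > t_gather))[0]
            if cand.size == 0:
                cand = np.array([idx])
            if cand.size == members.size and np.array_equal(np.sort(cand), np.sort(members)):
                break
            members = cand
            centroid = np.median(x[members], axis=0)
        unassigned[members] = False
        canopies.append(np.sort(members))
        centroids.append(np.median(x[members], axis=0))

    # merge canopies whose centroids correlate above t_merge (transitive)
    n = len(canopies)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = centroids[i], centroids[j]
            r = _pearson_to_centroid(ci[None, :], cj)[0]
            if np.isfinite(r) and r > t_merge:
                parent[find(i)] = find(j)

    merged: dict[int, list[int]] = {}
    for i in range(n):
        merged.setdefault(find(i), []).extend(canopies[i].tolist())

    cags = []
    for group in merged.values():
        if len(group) < min_size:
            continue
        member_ids = sorted(features[i] for i in group)
        centroid = pd.Series(
            np.median(x[sorted(group)], axis=0), index=profiles.samples
        )
        cags.append(CAG(id="", members=member_ids, centroid=centroid))
    # deterministic ids: order by size desc then first member
    cags.sort(key=lambda c: (-c.size, c.members[0]))
    for i, cag in enumerate(cags):
        cag.id = f"CAG{i + 1:04d}"
    return cags


def annotate_cag(cag: CAG, species_tags: dict[str, str] | None = None) -> CAG:
    """Assign the majority species when its member fraction is >= 0.8 (inclusive).

    ``species_tags`` maps member gene-family id to species; when omitted,
    tags are parsed from the members' ``feature|taxon`` stratification, with
    the ``unclassified`` suffix kept as its own pseudo-species.
    """
    if not cag.members:
        raise ValueError("cannot annotate an empty CAG")
    if species_tags is None:
        species_tags = {m: parse_stratification(m)[1] or "unclassified" for m in cag.members}
    tags = pd.Series([species_tags.get(m, "unclassified") for m in cag.members])
    counts = tags.value_counts()
    top, frac = counts.index[0], counts.iloc[0] / len(cag.members)
    cag.species = str(top) if frac >= ANNOTATION_FRACTION else "unclassified"
    return cag


def centroid_table(cags: list[CAG]) -> AbundanceTable:
    """Stack CAG centroid profiles into an abundance table (CAGs x samples)."""
    data = pd.DataFrame({c.id: c.centroid for c in cags}).T
    data.index.name = None
    return AbundanceTable(data.clip(lower=0.0), normalization="raw")


def cag_enrichment(
    cags: list[CAG],
    metadata: SampleMetadata,
    contrast: diffabund.ContrastSpec | None = None,
) -> list[CAG]:
    """Wilcoxon + BH group comparison of each CAG's centroid abundance."""
    if not cags:
        return cags
    table = centroid_table(cags)
    res = diffabund.differential_features(
        table, metadata, contrast=contrast, per_rank=False
    ).set_index("feature")
    for cag in cags:
        row = res.loc[cag.id]
        cag.p = float(row["p"])
        cag.q = float(row["q"])
        cag.enriched = row["enriched"] if bool(row["significant"]) else "none"
    return cags


@dataclass
class CAGNetwork:
    """Thresholded Pearson-correlation graph over CAG centroids."""

    graph: nx.Graph
    edges: pd.DataFrame  # cag_a, cag_b, r, sign

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, attrs in g.nodes(data=True):  # GraphML cannot carry None
            for k, v in attrs.items():
                if v is None:
                    attrs[k] = ""
        nx.write_graphml(g, path)


def build_network(
    cags: list[CAG],
    pos_threshold: float = 0.5,
    neg_threshold: float = -0.2,
) -> CAGNetwork:
    """Correlation network over CAG centroids.

    Every kept edge satisfies ``r > pos_threshold`` (sign "positive") or
    ``r < neg_threshold`` (sign "negative"); no self-edges. Node attributes
    carry the CAG size, species annotation and enrichment call.
    """
    if len(cags) < 2:
        raise ValueError("need at least two CAGs to build a network")
    g = nx.Graph()
    for c in cags:
        g.add_node(c.id, size=c.size, species=c.species, enriched=c.enriched)
    rows = []
    for i in range(len(cags)):
        for j in range(i + 1, len(cags)):
            a, b = cags[i], cags[j]
            av, bv = a.centroid.to_numpy(), b.centroid.to_numpy()
            if av.std() == 0 or bv.std() == 0:
                continue
            r = float(np.corrcoef(av, bv)[0, 1])
            if r > pos_threshold:
                sign = "positive"
            elif r < neg_threshold:
                sign = "negative"
            else:
                continue
            g.add_edge(a.id, b.id, r=r, sign=sign)
            rows.append({"cag_a": a.id, "cag_b": b.id, "r": r, "sign": sign})
    edges = pd.DataFrame(rows, columns=["cag_a", "cag_b", "r", "sign"])
    return CAGNetwork(g, edges)


def membership_frame(cags: list[CAG]) -> pd.DataFrame:
    """Long-format membership table: cag_id, gene_family, species tag."""
    rows = []
    for c in cags:
        for m in c.members:
            rows.append(
                {
                    "cag_id": c.id,
                    "gene_family": m,
                    "species": parse_stratification(m)[1] or "unclassified",
                }
            )
    return pd.DataFrame(rows, columns=["cag_id", "gene_family", "species"])
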