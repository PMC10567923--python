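"""ROI atlas of the stress-related network.

21 regions of interest: nine bilateral structures (amygdala, hypothalamus,
caudate, putamen, anterior/medial/posterior hippocampus, anterior/posterior
insula) plus three midline cortical regions (PCC, dACC, vmPFC).  Bilateral
pairing maps the 21 ROIs onto 12 anatomical regions; all unordered ROI pairs
form the 210 connectivity edges, each assigned to one of four subnetworks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

Edge = tuple[str, str]

_BILATERAL = (
    "amygdala", "hypothalamus", "caudate", "putamen",
    "hippocampus_ant", "hippocampus_med", "hippocampus_post",
)
_MIDLINE = ("pcc", "dacc", "vmpfc")
_BILATERAL_TAIL = ("insula_ant", "insula_post")

# broad anatomical class used by the default subnetwork partition
_CLASS = {
    "amygdala": "limbic", "hypothalamus": "limbic",
    "caudate": "striatal", "putamen": "striatal",
    "hippocampus_ant": "hippocampal", "hippocampus_med": "hippocampal",
    "hippocampus_post": "hippocampal",
    "insula_ant": "cortical", "insula_post": "cortical",
    "pcc": "cortical", "dacc": "cortical", "vmpfc": "cortical",
}


@dataclass(frozen=True)
class RoiAtlas:
    """ROI labels with hemisphere/region maps and an edge->subnetwork map.

    ``rois`` fixes the canonical ordering: edges are the upper triangle of the
    ROI x ROI matrix in this order, and the first ROI of each pair is the
    dependent ("target") ROI of that edge's model.
    """

    rois: tuple[str, ...]
    region: dict[str, str]
    hemisphere: dict[str, str]
    subnetwork: dict[Edge, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.rois)) != len(self.rois):
            raise ValueError("duplicate ROI labels")
        for r in self.rois:
            if r not in self.region or r not in self.hemisphere:
                raise ValueError(f"ROI {r!r} missing region/hemisphere entry")
        if self.subnetwork:
            missing = set(self.edges()) - set(self.subnetwork)
            if missing:
                raise ValueError(f"{len(missing)} edges lack a subnetwork")

    # -- structure ---------------------------------------------------------

    def edges(self) -> list[Edge]:
        """All unordered ROI pairs in canonical (upper-triangle) order."""
        n = len(self.rois)
        return [(self.rois[i], self.rois[j])
                for i in range(n) for j in range(i + 1, n)]

    @property
    def n_edges(self) -> int:
        n = len(self.rois)
        return n * (n - 1) // 2

    @property
    def regions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.rois:
            seen.setdefault(self.region[r], None)
        return tuple(seen)

    @property
    def subnetworks(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.subnetwork.values())))

    def rois_of_region(self, region: str) -> list[str]:
        return [r for r in self.rois if self.region[r] == region]

    def edges_of_subnetwork(self, k: int) -> list[Edge]:
        return [e for e in self.edges() if self.subnetwork[e] == k]

    # -- constructors --------------------------------------------------------

    @classmethod
    def stress_network(cls) -> "RoiAtlas":
        """The 21-ROI stress network with the anatomical default subnetworks.

        Ordering note: a bilateral ROI is placed last so that, under the
        upper-triangle dependent-ROI convention, every anatomical region keeps
        at least one model in which one of its ROIs is the dependent variable.
        """
        rois: list[str] = []
        region: dict[str, str] = {}
        hemi: dict[str, str] = {}
        for base in _BILATERAL:
            for h in ("l", "r"):
                name = f"{base}_{h}"
                rois.append(name)
                region[name] = base
                hemi[name] = h
        for base in _MIDLINE:
            rois.append(base)
            region[base] = base
            hemi[base] = "m"
        for base in _BILATERAL_TAIL:
            for h in ("l", "r"):
                name = f"{base}_{h}"
                rois.append(name)
                region[name] = base
                hemi[name] = h
        atlas = cls(tuple(rois), region, hemi)
        sub = default_subnetworks(atlas)
        return cls(tuple(rois), region, hemi, sub)

    @classmethod
    def toy(cls, n: int, n_subnetworks: int = 4) -> "RoiAtlas":
        """Small atlas for simulation studies (roi01..roiNN, paired into
        pseudo-bilateral regions so every region keeps a dependent-ROI model;
        edges assigned round-robin to subnetworks)."""
        rois = tuple(f"roi{i:02d}" for i in range(1, n + 1))
        region: dict[str, str] = {}
        hemi: dict[str, str] = {}
        start = 0
        if n % 2 == 1:  # singleton region first, never last in order
            region[rois[0]] = "reg00"
            hemi[rois[0]] = "m"
            start = 1
        for k, i in enumerate(range(start, n, 2)):
            region[rois[i]] = f"reg{k + 1:02d}"
            region[rois[i + 1]] = f"reg{k + 1:02d}"
            hemi[rois[i]] = "l"
            hemi[rois[i + 1]] = "r"
        atlas = cls(rois, region, hemi)
        k = min(n_subnetworks, atlas.n_edges)
        sub = {e: (i % k) + 1 for i, e in enumerate(atlas.edges())}
        return cls(rois, region, hemi, sub)

    # -- I/O -----------------------------------------------------------------

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        roi_df = pd.DataFrame({
            "roi": list(self.rois),
            "hemisphere": [self.hemisphere[r] for r in self.rois],
            "region": [self.region[r] for r in self.rois],
        })
        edge_df = pd.DataFrame(
            [(a, b, self.subnetwork.get((a, b), 0)) for a, b in self.edges()],
            columns=["roi_a", "roi_b", "subnetwork"])
        return roi_df, edge_df

    @classmethod
    def from_frames(cls, roi_df: pd.DataFrame,
                    edge_df: pd.DataFrame | None = None) -> "RoiAtlas":
        rois = tuple(roi_df["roi"])
        region = dict(zip(roi_df["roi"], roi_df["region"]))
        hemi = dict(zip(roi_df["roi"], roi_df["hemisphere"]))
        sub: dict[Edge, int] = {}
        if edge_df is not None:
            for _, r in edge_df.iterrows():
                sub[(r["roi_a"], r["roi_b"])] = int(r["subnetwork"])
        return cls(rois, region, hemi, sub)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        roi_df, edge_df = self.to_frames()
        roi_df.to_csv(path / "atlas_rois.tsv", sep="\t", index=False)
        edge_df.to_csv(path / "atlas_edges.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "RoiAtlas":
        path = Path(path)
        roi_df = pd.read_csv(path / "atlas_rois.tsv", sep="\t")
        edge_path = path / "atlas_edges.tsv"
        edge_df = pd.read_csv(edge_path, sep="\t") if edge_path.exists() else None
        return cls.from_frames(roi_df, edge_df)


def default_subnetworks(atlas: RoiAtlas) -> dict[Edge, int]:
    """Deterministic anatomy-based 4-way edge partition.

    1: cortico-cortical, 2: subcortico-subcortical, 3: cortical with
    hippocampal or limbic, 4: cortical with striatal.  Every edge of the full
    stress network falls in exactly one class.
    """
    out: dict[Edge, int] = {}
    for a, b in atlas.edges():
        ca = _CLASS.get(atlas.region[a], "cortical")
        cb = _CLASS.get(atlas.region[b], "cortical")
        cortical = (ca == "cortical") + (cb == "cortical")
        if cortical == 2:
            out[(a, b)] = 1
        elif cortical == 0:
            out[(a, b)] = 2
        else:
            other = cb if ca == "cortical" else ca
            out[(a, b)] = 4 if other == "striatal" else 3
    return out


def cluster_edge_subnetworks(trajectories: np.ndarray, edges: list[Edge],
                             n_subnetworks: int = 4, seed: int = 0) -> dict[Edge, int]:
    """Data-driven subnetworks: k-means on group-mean FC trajectories.

    ``trajectories`` is (n_edges, n_timepoints) of group-level connectivity
    estimates.  Returns an edge->subnetwork map with labels 1..k, relabelled
    deterministically by cluster size (largest first) so runs are reproducible.
    """
    from sklearn.cluster import KMeans

    if trajectories.shape[0] != len(edges):
        raise ValueError("trajectory rows must match edges")
    km = KMeans(n_clusters=n_subnetworks, n_init=10, random_state=seed)
    raw = km.fit_predict(trajectories)
    order = np.argsort([-np.sum(raw == k) for k in range(n_subnetworks)],
                       kind="stable")
    relabel = {int(old): i + 1 for i, old in enumerate(order)}
    return {e: relabel[int(lbl)] for e, lbl in zip(edges, raw)}
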