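"""Mixup augmentation of 12-lead QRS beats with an anatomical neighbor rule.

Augmented beats are convex combinations of two parents,
``x_hat = lam * x_i + (1 - lam) * x_j`` with ``lam ~ Beta(alpha, beta)``
(defaults alpha=5, beta=1.5).  The dominant parent's label is adopted
(``y_i`` iff ``lam > 0.5``) and ``lam`` is kept as the sample weight for
training.  In sublocation mode the second parent may only come from the same
sublocation or a graph-adjacent one, so mixtures never interpolate between
anatomically distant sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .synthetic_ecg import Dataset, SOOLabel, SUBLOCATION_CHAMBER

__all__ = [
    "MixupConfig",
    "AdjacencyGraph",
    "AugmentedSample",
    "DEFAULT_ADJACENCY_EDGES",
    "mixup_pair",
    "augment_dataset",
    "MixupAugmenter",
]

#: Default sublocation adjacency: the aortic-cusp neighborhood for the LVOT
#: sites, the three right-sided sites forming a triangle, and no
#: cross-chamber edges.
DEFAULT_ADJACENCY_EDGES: tuple[tuple[str, str], ...] = (
    ("LCC", "LCC-RCC-commissure"),
    ("LCC-RCC-commissure", "RCC"),
    ("RCC", "NCC"),
    ("LCC", "NCC"),
    ("AMC", "LCC"),
    ("AMC", "NCC"),
    ("LV-summit", "LCC"),
    ("LV-summit", "RCC"),
    ("anteroseptal-RV", "posteroseptal-RV"),
    ("anteroseptal-RV", "RFW"),
    ("posteroseptal-RV", "RFW"),
)


@dataclass(frozen=True)
class MixupConfig:
    alpha: float = 5.0
    beta: float = 1.5
    ratio: int = 3
    label_mode: str = "chamber"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shapes alpha and beta must be > 0")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if self.label_mode not in ("chamber", "sublocation"):
            raise ValueError("label_mode must be 'chamber' or 'sublocation'")


class AdjacencyGraph:
    """Undirected, loop-free graph over the nine sublocations."""

    def __init__(self, edges=DEFAULT_ADJACENCY_EDGES):
        adj: dict[str, set[str]] = {s: set() for s in SUBLOCATION_CHAMBER}
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r} not allowed")
            for node in (a, b):
                if node not in adj:
                    raise ValueError(f"unknown sublocation {node!r}")
            adj[a].add(b)
            adj[b].add(a)
        isolated = [s for s, nb in adj.items() if not nb]
        if isolated:
            raise ValueError(f"sublocations without neighbors: {isolated}")
        self._adj = adj

    def neighbors(self, sublocation: str) -> frozenset[str]:
        return frozenset(self._adj[sublocation])

    def is_adjacent(self, a: str, b: str) -> bool:
        return b in self._adj[a]

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        seen = set()
        out = []
        for a, nbs in sorted(self._adj.items()):
            for b in sorted(nbs):
                if (b, a) not in seen:
                    seen.add((a, b))
                    out.append((a, b))
        return tuple(out)

    @classmethod
    def from_file(cls, path) -> "AdjacencyGraph":
        """Read an edge-list text file: one ``a<TAB-or-space>b`` pair per line."""
        edges = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"malformed edge line: {line!r}")
                edges.append((parts[0], parts[1]))
        return cls(edges)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for a, b in self.edges:
                fh.write(f"{a}\t{b}\n")


@dataclass
class AugmentedSample:
    """Convex beat mixture carrying its mixing weight and adopted label."""

    x_hat: np.ndarray
    label: SOOLabel
    lam: float
    parent_ids: tuple
    fs: float | None = None
    qrs_onset: int | None = None
    qrs_offset: int | None = None
    r_peak: int | None = None
    record_id: str | None = None

    @property
    def signal(self) -> np.ndarray:
        return self.x_hat

    @property
    def sample_weight(self) -> float:
        return self.lam


def mixup_pair(x_i, x_j, y_i: SOOLabel, y_j: SOOLabel,
               lam: float) -> AugmentedSample:
    """Mix two beats: ``x_hat = lam x_i + (1-lam) x_j``, dominant label."""
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if x_i.shape != x_j.shape:
        raise ValueError(f"shape mismatch: {x_i.shape} vs {x_j.shape}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    x_hat = lam * x_i + (1.0 - lam) * x_j
    label = y_i if lam > 0.5 else y_j
    return AugmentedSample(x_hat=x_hat, label=label, lam=float(lam),
                           parent_ids=(None, None))


def augment_dataset(
    dataset: Dataset,
    config: MixupConfig | None = None,
    graph: AdjacencyGraph | None = None,
) -> Dataset:
    """Generate ``ratio x len(dataset)`` mixup samples.

    Each original beat acts as first parent exactly ``ratio`` times; the
    second parent is drawn uniformly from all other beats (chamber mode) or
    only from beats of the same or a graph-adjacent sublocation
    (sublocation mode).
    """
    if config is None:
        config = MixupConfig()
    records = dataset.records
    n = len(records)
    if n < 2:
        raise ValueError("mixup requires at least 2 records")

    if config.label_mode == "sublocation":
        if graph is None:
            graph = AdjacencyGraph()
        by_subloc: dict[str, list[int]] = {}
        for idx, rec in enumerate(records):
            by_subloc.setdefault(rec.label.sublocation, []).append(idx)
        pools: dict[str, np.ndarray] = {}
        for subloc in by_subloc:
            allowed = {subloc} | set(graph.neighbors(subloc))
            pool = [i for s in allowed for i in by_subloc.get(s, [])]
            pools[subloc] = np.array(sorted(pool), dtype=int)
            if len(pools[subloc]) < 2:
                raise ValueError(
                    f"sublocation {subloc!r} has no neighboring records to mix with"
                )

    rng = np.random.default_rng([config.seed, 4242])
    samples: list[AugmentedSample] = []
    for k in range(config.ratio * n):
        i = k % n
        rec_i = records[i]
        if config.label_mode == "chamber":
            j = int(rng.integers(n - 1))
            if j >= i:
                j += 1
        else:
            pool = pools[rec_i.label.sublocation]
            while True:
                j = int(pool[rng.integers(len(pool))])
                if j != i:
                    break
        rec_j = records[j]
        lam = float(rng.beta(config.alpha, config.beta))
        sample = mixup_pair(rec_i.signal, rec_j.signal,
                            rec_i.label, rec_j.label, lam)
        dominant = rec_i if lam > 0.5 else rec_j
        sample.fs = dataset.fs
        sample.qrs_onset = min(rec_i.qrs_onset, rec_j.qrs_onset)
        sample.qrs_offset = max(rec_i.qrs_offset, rec_j.qrs_offset)
        sample.r_peak = dominant.r_peak
        sample.parent_ids = (rec_i.record_id or i, rec_j.record_id or j)
        sample.record_id = f"aug-{k:05d}"
        samples.append(sample)

    return Dataset(
        records=samples,
        provenance="augmented",
        metadata={
            "mixup": {
                "alpha": config.alpha,
                "beta": config.beta,
                "ratio": config.ratio,
                "label_mode": config.label_mode,
                "seed": config.seed,
            },
            "n_input": n,
        },
    )


class MixupAugmenter(BaseEstimator):
    """Estimator-style wrapper around :func:`augment_dataset`."""

    def __init__(self, alpha: float = 5.0, beta: float = 1.5, ratio: int = 3,
                 label_mode: str = "chamber", seed: int = 0, graph=None):
        self.alpha = alpha
        self.beta = beta
        self.ratio = ratio
        self.label_mode = label_mode
        self.seed = seed
        self.graph = graph

    def fit(self, X=None, y=None):
        self.config_ = MixupConfig(alpha=self.alpha, beta=self.beta,
                                   ratio=self.ratio,
                                   label_mode=self.label_mode, seed=self.seed)
        return self

    def augment(self, dataset: Dataset) -> Dataset:
        self.fit()
        return augment_dataset(dataset, self.config_, self.graph)
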