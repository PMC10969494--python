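"""Areal adjacency graphs and spatial autocorrelation diagnostics.

The spatial backbone of a disease-mapping analysis is a binary contiguity
graph over the areal units (zip codes, lattice cells, ...): ``W[i, j] = 1``
iff units *i* and *j* share a border.  From it we derive the diagonal
neighbour-count matrix ``M``, the proper-CAR structure matrix
``Q = M - rho * W``, and the eigenvalue-scaled adjacency ``W / lambda_max(W)``
used by the covariate-imputation GMRF so its autocorrelation parameter lives
in (0, 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


class IsolatedNodeError(ValueError):
    """A node with no neighbours cannot enter a spatial model."""


class GraphValidationError(ValueError):
    pass


class AdjacencyGraph:
    """Symmetric binary contiguity graph over ordered areal units.

    Parameters
    ----------
    node_ids
        Ordered unit identifiers (unique).
    W
        N x N symmetric binary adjacency with zero diagonal (dense or sparse).
    allow_isolated
        Permit degree-0 nodes.  Diagnostics tolerate them; spatial model
        fitting does not (mirroring the removal of units without credible
        spatial adjacency from the analysis set).
    """

    def __init__(self, node_ids: Sequence, W, *, allow_isolated: bool = False):
        ids = list(node_ids)
        if len(set(map(str, ids))) != len(ids):
            raise GraphValidationError("node IDs must be unique")
        W = sp.csr_matrix(W, dtype=float)
        if W.shape[0] != W.shape[1] or W.shape[0] != len(ids):
            raise GraphValidationError("W must be square and match node_ids")
        if (abs(W - W.T) > 1e-12).nnz:
            raise GraphValidationError("adjacency matrix must be symmetric")
        if W.diagonal().any():
            raise GraphValidationError("adjacency matrix must have zero diagonal")
        data = W.data
        if data.size and not np.all((data == 0) | (data == 1)):
            raise GraphValidationError("adjacency entries must be 0/1")
        W.eliminate_zeros()
        self.node_ids = ids
        self.W = W
        self._index = {str(i): k for k, i in enumerate(ids)}
        deg = np.asarray(W.sum(axis=1)).ravel()
        self.M = deg
        if not allow_isolated and (deg == 0).any():
            bad = [str(ids[k]) for k in np.flatnonzero(deg == 0)]
            raise IsolatedNodeError(
                f"isolated unit(s) without neighbours: {', '.join(bad)}; "
                "drop them or pass allow_isolated=True for diagnostics"
            )
        self._cache: dict = {}

    # -- basic properties ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.node_ids)

    def index_of(self, node_id) -> int:
        return self._index[str(node_id)]

    @property
    def n_components(self) -> int:
        if "ncomp" not in self._cache:
            ncomp, labels = connected_components(self.W, directed=False)
            self._cache["ncomp"] = ncomp
            self._cache["component_labels"] = labels
        return self._cache["ncomp"]

    @property
    def component_labels(self) -> np.ndarray:
        self.n_components
        return self._cache["component_labels"]

    @property
    def is_connected(self) -> bool:
        return self.n_components == 1

    # -- spectral quantities (cached; reused heavily by the sampler) --------

    @property
    def lambda_max(self) -> float:
        """Largest eigenvalue of W (Perron root)."""
        if "lam_max" not in self._cache:
            if self.W.nnz == 0:
                raise GraphValidationError("graph has no edges; cannot scale W")
            if self.n <= 3:
                lam = float(np.linalg.eigvalsh(self.W.toarray()).max())
            else:
                # deterministic start vector: the default random v0 would make
                # the last bits of lambda_max depend on global RNG state
                lam = float(
                    sp.linalg.eigsh(self.W, k=1, which="LA",
                                    return_eigenvectors=False,
                                    v0=np.ones(self.n))[0]
                )
            self._cache["lam_max"] = lam
        return self._cache["lam_max"]

    @property
    def W_scaled(self) -> sp.csr_matrix:
        """W divided by its largest eigenvalue (spectral radius 1)."""
        if "W_scaled" not in self._cache:
            self._cache["W_scaled"] = (self.W / self.lambda_max).tocsr()
        return self._cache["W_scaled"]

    @property
    def scaled_eigvals(self) -> np.ndarray:
        """Eigenvalues of W_scaled (dense once per graph; used for log-dets)."""
        if "scaled_eig" not in self._cache:
            self._cache["scaled_eig"] = np.linalg.eigvalsh(self.W_scaled.toarray())
        return self._cache["scaled_eig"]

    @property
    def car_eigvals(self) -> np.ndarray:
        """Generalized eigenvalues nu of (W, M): log det(M - rho W) =
        log det M + sum log(1 - rho * nu_i).  Requires all degrees >= 1."""
        if "car_eig" not in self._cache:
            if (self.M == 0).any():
                raise IsolatedNodeError("CAR spectrum undefined with isolated nodes")
            d = 1.0 / np.sqrt(self.M)
            A = self.W.toarray() * d[:, None] * d[None, :]
            self._cache["car_eig"] = np.linalg.eigvalsh(A)
        return self._cache["car_eig"]

    @property
    def coloring(self) -> list[np.ndarray]:
        """Greedy proper colouring; same-colour nodes are mutually
        non-adjacent, so their CAR full conditionals are independent and can
        be updated as one vectorised block."""
        if "colors" not in self._cache:
            color = np.full(self.n, -1, dtype=int)
            indptr, indices = self.W.indptr, self.W.indices
            order = np.argsort(-self.M, kind="stable")
            for i in order:
                nb = color[indices[indptr[i]:indptr[i + 1]]]
                used = set(nb[nb >= 0].tolist())
                c = 0
                while c in used:
                    c += 1
                color[i] = c
            self._cache["colors"] = [
                np.flatnonzero(color == c) for c in range(color.max() + 1)
            ]
        return self._cache["colors"]

    # -- manipulation -------------------------------------------------------

    def subset(self, keep: Sequence[int], *, allow_isolated: bool = False) -> "AdjacencyGraph":
        keep = np.asarray(keep, dtype=int)
        ids = [self.node_ids[k] for k in keep]
        W = self.W[keep][:, keep]
        return AdjacencyGraph(ids, W, allow_isolated=allow_isolated)

    def edges(self) -> list[tuple]:
        coo = sp.triu(self.W).tocoo()
        return [(self.node_ids[i], self.node_ids[j]) for i, j in zip(coo.row, coo.col)]

    def to_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            for a, b in self.edges():
                fh.write(f"{a}\t{b}\n")

    def to_mtx(self, path) -> None:
        from scipy.io import mmwrite

        mmwrite(str(path), self.W.tocoo())


# ---------------------------------------------------------------------------
# construction


def from_edge_list(
    edges: Iterable[tuple],
    node_ids: Sequence | None = None,
    *,
    allow_isolated: bool = False,
) -> AdjacencyGraph:
    """Build a graph from unit-ID pairs.

    When ``node_ids`` is omitted the node set is taken from the edges (sorted
    by first appearance); pass it explicitly so isolated units are detected.
    Symmetry is implied: each undirected pair needs to appear only once, and a
    contradictory duplicate is impossible in a binary graph.
    """
    edges = list(edges)
    if node_ids is None:
        seen: dict = {}
        for a, b in edges:
            seen.setdefault(str(a), a)
            seen.setdefault(str(b), b)
        node_ids = list(seen.values())
    idx = {str(i): k for k, i in enumerate(node_ids)}
    rows, cols = [], []
    for a, b in edges:
        ka, kb = str(a), str(b)
        if ka not in idx or kb not in idx:
            raise GraphValidationError(f"edge ({a}, {b}) references unknown unit")
        if ka == kb:
            raise GraphValidationError(f"self-edge on unit {a}")
        rows += [idx[ka], idx[kb]]
        cols += [idx[kb], idx[ka]]
    n = len(node_ids)
    W = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    W.data[:] = 1.0  # collapse duplicates
    return AdjacencyGraph(node_ids, W, allow_isolated=allow_isolated)


def read_edge_list(path, node_ids=None, *, allow_isolated: bool = False) -> AdjacencyGraph:
    """Two-column delimited text of unit-ID pairs (tab, comma or whitespace)."""
    edges = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) < 2:
            raise GraphValidationError(f"malformed edge line: {raw!r}")
        edges.append((parts[0], parts[1]))
    return from_edge_list(edges, node_ids, allow_isolated=allow_isolated)


def from_polygons(
    source,
    id_field: str = "id",
    *,
    rule: str = "queen",
    allow_isolated: bool = False,
) -> AdjacencyGraph:
    """Contiguity graph from polygon geometries (GeoJSON file or mapping).

    ``rule='queen'`` (default): any shared boundary point makes a neighbour
    pair.  ``rule='rook'``: the shared boundary must have positive length.
    """
    from shapely.geometry import shape
    from shapely.strtree import STRtree

    if rule not in ("queen", "rook"):
        raise ValueError("rule must be 'queen' or 'rook'")
    if isinstance(source, (str, Path)):
        source = json.loads(Path(source).read_text())
    feats = source["features"] if isinstance(source, dict) else list(source)
    ids, geoms = [], []
    for f in feats:
        if isinstance(f, dict) and "geometry" in f:
            ids.append(f.get("properties", {}).get(id_field))
            geoms.append(shape(f["geometry"]))
        else:  # (id, geometry) pair
            ids.append(f[0])
            geoms.append(shape(f[1]) if isinstance(f[1], dict) else f[1])
    if any(i is None for i in ids):
        raise GraphValidationError(f"polygon feature missing ID field {id_field!r}")
    for i, g in zip(ids, geoms):
        if not g.is_valid:
            raise GraphValidationError(f"invalid polygon geometry for unit {i}")
    tree = STRtree(geoms)
    edges = []
    for a, ga in enumerate(geoms):
        for b in tree.query(ga):
            b = int(b)
            if b <= a:
                continue
            inter = ga.boundary.intersection(geoms[b].boundary)
            if inter.is_empty:
                continue
            if rule == "rook" and inter.length <= 0:
                continue
            edges.append((ids[a], ids[b]))
    return from_edge_list(edges, ids, allow_isolated=allow_isolated)


def grid(nrows: int, ncols: int, *, rule: str = "rook") -> AdjacencyGraph:
    """Regular lattice graph; the synthetic default is a 30 x 30 rook lattice."""
    if rule not in ("rook", "queen"):
        raise ValueError("rule must be 'rook' or 'queen'")
    ids = [f"g{r}_{c}" for r in range(nrows) for c in range(ncols)]
    edges = []
    for r in range(nrows):
        for c in range(ncols):
            a = r * ncols + c
            if c + 1 < ncols:
                edges.append((ids[a], ids[a + 1]))
            if r + 1 < nrows:
                edges.append((ids[a], ids[a + ncols]))
            if rule == "queen" and r + 1 < nrows:
                if c + 1 < ncols:
                    edges.append((ids[a], ids[a + ncols + 1]))
                if c - 1 >= 0:
                    edges.append((ids[a], ids[a + ncols - 1]))
    return from_edge_list(edges, ids)


def build_adjacency(source, **kwargs) -> AdjacencyGraph:
    """Dispatch on source type: AdjacencyGraph (pass-through), edge iterable,
    edge-list path (.tsv/.csv/.txt/.edges) or GeoJSON path/mapping."""
    if isinstance(source, AdjacencyGraph):
        return source
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.suffix.lower() in (".geojson", ".json"):
            return from_polygons(p, **kwargs)
        return read_edge_list(p, **kwargs)
    if isinstance(source, dict):
        return from_polygons(source, **kwargs)
    return from_edge_list(source, **kwargs)


# ---------------------------------------------------------------------------
# CAR structure matrix and scaling


def structure_matrix(graph: AdjacencyGraph, rho: float, *, allow_intrinsic: bool = False):
    """Proper-CAR structure matrix ``Q = M - rho * W`` (sparse symmetric).

    Positive definite for rho in [0, 1) on a graph whose nodes all have at
    least one neighbour.  ``rho = 1`` gives the intrinsic (singular) variant
    and must be requested explicitly.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho={rho} outside [0, 1]")
    if rho == 1.0 and not allow_intrinsic:
        raise ValueError("rho = 1 is the improper intrinsic model; pass allow_intrinsic=True")
    return (sp.diags(graph.M) - rho * graph.W).tocsr()


def scale_adjacency(graph: AdjacencyGraph) -> sp.csr_matrix:
    """W divided by its largest eigenvalue, so the imputation GMRF's
    autocorrelation parameter can range over (0, 1)."""
    return graph.W_scaled


# ---------------------------------------------------------------------------
# Moran's I


@dataclass
class MoransIResult:
    statistic: float
    p_value: float | None
    expected: float
    n_perm: int

    def __iter__(self):  # (I, p) unpacking convenience
        yield self.statistic
        yield self.p_value


def morans_i(
    values,
    graph: AdjacencyGraph,
    n_perm: int = 9999,
    seed: int | None = None,
    *,
    row_standardize: bool = False,
) -> MoransIResult:
    """Global Moran's I with a one-sided Monte-Carlo permutation p-value.

    I = (N / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centred
    values and S0 = sum_ij w_ij.  The permutation tail probability counts the
    observed statistic in the reference set:
    p = (1 + #{I_perm >= I_obs}) / (n_perm + 1).
    """
    z = np.asarray(values, dtype=float)
    if z.ndim != 1 or z.size != graph.n:
        raise ValueError("values length must equal the node count")
    if np.isnan(z).any():
        raise ValueError("values contain NaN")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("constant input: Moran's I undefined (zero variance)")
    Wm = graph.W
    if row_standardize:
        deg = graph.M.copy()
        deg[deg == 0] = 1.0
        Wm = sp.diags(1.0 / deg) @ graph.W
    s0 = float(Wm.sum())
    n = graph.n
    scale = n / s0

    def stat(v):
        return scale * float(v @ (Wm @ v)) / float(v @ v)

    i_obs = stat(z)
    p = None
    if n_perm and n_perm >= 1:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(int(n_perm)):
            if stat(rng.permutation(z)) >= i_obs:
                exceed += 1
        p = (1.0 + exceed) / (n_perm + 1.0)
    return MoransIResult(i_obs, p, -1.0 / (n - 1), int(n_perm or 0))
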