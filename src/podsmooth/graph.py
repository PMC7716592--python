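"""Spatial neighbourhood structure for proper CAR (PCAR) random effects.

A :class:`SpatialGraph` holds the binary contiguity matrix ``W`` of a set of
small areas, the diagonal degree matrix ``D`` (neighbour counts) and the
eigenvalues of the symmetrized adjacency ``D^{-1/2} W D^{-1/2}``.  Those
eigenvalues determine the open interval of spatial-correlation parameters
``gamma`` for which the PCAR precision matrix ``D - gamma*W`` is positive
definite, and give an O(S) expression for its log-determinant,

    log det(D - gamma*W) = sum_s log D_s + sum_i log(1 - gamma*lambda_i),

so the PCAR log-density can be evaluated cheaply inside an MCMC loop.

Only binary first-order contiguity is supported: that is the structure the
PCAR formulation assumes, and areas without any neighbour are rejected
outright because ``D - gamma*W`` is then singular at gamma-independent rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpatialGraph",
    "build_graph",
    "load_adjacency",
    "parse_edge_list",
    "parse_gal",
    "pcar_log_density",
]

#: samplers stay this far inside the open gamma support
GAMMA_MARGIN = 1e-6

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class SpatialGraph:
    """Validated binary contiguity structure over ``n_areas`` small areas.

    Attributes
    ----------
    area_ids:
        Ordered area labels; all matrices follow this order.
    W:
        Dense symmetric 0/1 adjacency with zero diagonal, shape (S, S).
    D:
        Neighbour counts (row sums of W), shape (S,); every entry >= 1.
    eigenvalues:
        Eigenvalues of ``D^{-1/2} W D^{-1/2}`` in ascending order.
    """

    area_ids: tuple
    W: np.ndarray
    D: np.ndarray
    eigenvalues: np.ndarray = field(repr=False)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def gamma_support(self) -> tuple[float, float]:
        """Open interval of valid spatial-correlation parameters.

        Returns ``(1/lambda_min, 1/lambda_max)``; contains 0, and the upper
        endpoint is 1 for a connected graph.
        """
        lam = self.eigenvalues
        return (1.0 / lam[0], 1.0 / lam[-1])

    def contains_gamma(self, gamma: float, margin: float = 0.0) -> bool:
        lo, hi = self.gamma_support
        return lo + margin < gamma < hi - margin

    def edges(self) -> list[tuple]:
        """Edge list as pairs of area ids, each undirected edge once."""
        ii, jj = np.nonzero(np.triu(self.W))
        return [(self.area_ids[i], self.area_ids[j]) for i, j in zip(ii, jj)]

    def index_of(self, area_id) -> int:
        return self.area_ids.index(area_id)


def build_graph(edges: Iterable[tuple], area_ids: Sequence) -> SpatialGraph:
    """Construct a :class:`SpatialGraph` from an undirected edge list.

    ``area_ids`` fixes the matrix ordering (it always comes from the mortality
    table, never from file order).  Duplicate or reversed edges collapse.

    Raises
    ------
    ValueError
        On unknown endpoints, self-edges, or isolated areas, naming the
        offending label.
    """
    ids = tuple(area_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("area_ids contains duplicates")
    index = {a: i for i, a in enumerate(ids)}
    S = len(ids)
    if S < 2:
        raise ValueError("need at least two areas")
    W = np.zeros((S, S))
    for a, b in edges:
        if a not in index:
            raise ValueError(f"edge endpoint {a!r} is not a known area id")
        if b not in index:
            raise ValueError(f"edge endpoint {b!r} is not a known area id")
        if a == b:
            raise ValueError(f"self-edge on area {a!r} is not allowed")
        i, j = index[a], index[b]
        W[i, j] = W[j, i] = 1.0
    D = W.sum(axis=1)
    isolated = np.nonzero(D == 0)[0]
    if isolated.size:
        raise ValueError(
            "isolated areas (no neighbours) are not supported: "
            + ", ".join(repr(ids[i]) for i in isolated)
        )
    dinv = 1.0 / np.sqrt(D)
    lam = np.linalg.eigvalsh(W * np.outer(dinv, dinv))
    return SpatialGraph(area_ids=ids, W=W, D=D, eigenvalues=lam)


def parse_edge_list(text: str) -> list[tuple[str, str]]:
    """Parse two-column delimited text of area-id pairs (header optional).

    A third column, if present, must be 1 for every row: general nonnegative
    weights are rejected rather than silently binarized.
    """
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if lineno == 1 and _looks_like_header(parts):
            continue
        if len(parts) not in (2, 3):
            raise ValueError(f"line {lineno}: expected 2 columns, got {len(parts)}")
        if len(parts) == 3:
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric weight {parts[2]!r}") from exc
            if w != 1.0:
                raise ValueError(
                    f"line {lineno}: weight {w} != 1; only binary contiguity is supported"
                )
        edges.append((parts[0], parts[1]))
    return edges


def _looks_like_header(parts: list[str]) -> bool:
    lowered = [p.lower() for p in parts[:2]]
    return lowered[0] in {"from", "source", "area", "area_id", "id1"} or lowered[1] in {
        "to",
        "target",
        "neighbor",
        "neighbour",
        "id2",
    }


def parse_gal(text: str) -> list[tuple[str, str]]:
    """Parse a GAL-style neighbour file into an edge list.

    Format: a count line (the area count, possibly preceded/followed by other
    tokens as written by common GIS tools), then per area a line ``id k``
    followed by a line with its k neighbour ids.
    """
    lines = [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError("empty GAL file")
    header = lines[0].split()
    n = None
    for tok in header:
        try:
            val = int(tok)
        except ValueError:
            continue
        if val > 0:
            n = val
            break
    if n is None:
        raise ValueError(f"cannot find area count in GAL header {lines[0]!r}")
    edges: list[tuple[str, str]] = []
    pos = 1
    for _ in range(n):
        if pos >= len(lines):
            raise ValueError("truncated GAL file: missing area block")
        head = lines[pos].split()
        if len(head) != 2:
            raise ValueError(f"malformed GAL block header {lines[pos]!r}")
        area, k = head[0], int(head[1])
        pos += 1
        neigh: list[str] = []
        while len(neigh) < k:
            if pos >= len(lines):
                raise ValueError(f"truncated GAL file: area {area!r} lists {k} neighbours")
            neigh.extend(lines[pos].split())
            pos += 1
        if len(neigh) != k:
            raise ValueError(f"area {area!r}: expected {k} neighbours, got {len(neigh)}")
        edges.extend((area, b) for b in neigh)
    return edges


def load_adjacency(source: str | Path, area_ids: Sequence) -> SpatialGraph:
    """Read an edge list or GAL-style weights file and build the graph.

    The format is auto-detected: a first line whose tokens are all integers
    (and that does not match any pair of area ids) is treated as a GAL header.
    """
    text = Path(source).read_text()
    first = next((ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")), "")
    tokens = first.split()
    known = set(map(str, area_ids))
    gal_like = (
        bool(tokens)
        and all(_is_int(t) for t in tokens)
        and not (len(tokens) >= 2 and tokens[0] in known and tokens[1] in known)
    )
    edges = parse_gal(text) if gal_like else parse_edge_list(text)
    mapped = {str(a): a for a in area_ids}
    out = []
    for a, b in edges:
        if a not in mapped:
            raise ValueError(f"edge endpoint {a!r} is not a known area id")
        if b not in mapped:
            raise ValueError(f"edge endpoint {b!r} is not a known area id")
        out.append((mapped[a], mapped[b]))
    return build_graph(out, area_ids)


def _is_int(tok: str) -> bool:
    try:
        int(tok)
    except ValueError:
        return False
    return True


def pcar_log_density(
    phi: np.ndarray, gamma: float, sigma2: float, graph: SpatialGraph
) -> float:
    """Log-density of the proper CAR distribution N(0, sigma2*(D - gamma*W)^{-1}).

    Includes the normalizing constant; the half log-determinant of the
    precision is computed from the precomputed eigenvalues so each call is
    O(S + edges).

    Raises
    ------
    ValueError
        If ``gamma`` lies outside the open support or ``sigma2 <= 0``.
    """
    if sigma2 <= 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    lo, hi = graph.gamma_support
    if not (lo < gamma < hi):
        raise ValueError(f"gamma={gamma} outside the open support ({lo}, {hi})")
    phi = np.asarray(phi, dtype=float)
    S = graph.n_areas
    if phi.shape != (S,):
        raise ValueError(f"phi must have shape ({S},), got {phi.shape}")
    logdet_prec = (
        np.log(graph.D).sum()
        + np.log1p(-gamma * graph.eigenvalues).sum()
        - S * np.log(sigma2)
    )
    quad = (graph.D * phi**2).sum() - gamma * (phi @ graph.W @ phi)
    return 0.5 * (logdet_prec - S * _LOG_2PI) - 0.5 * quad / sigma2
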