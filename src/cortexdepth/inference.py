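"""Vertexwise permutation GLM on cortical surfaces.

At every vertex a general linear model Y = X b + Z g is fitted, where X
is the regressor of interest (group indicator or a clinical variable) and
Z collects nuisance covariates — an intercept and global covariates (age,
sex) plus *vertexwise* nuisance maps (thickness, curvature) that differ
per vertex.  Inference uses threshold-free cluster enhancement (TFCE) of
the t-map as test statistic and the Draper-Stoneman permutation scheme:
the rows of X are permuted while Y and Z stay fixed, which preserves the
spatial dependence of the data in every permutation.

Familywise error control: within a contrast via the max-TFCE null over
vertices, and *across* modalities and contrasts via the joint max-TFCE
null over every result sharing the permutation schedule — results that
survive the within-contrast but not the joint correction are the
"trend-level" category.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sympy.utilities.iterables import multiset_permutations

from .surfaces import CorticalMesh

__all__ = [
    "SurfaceGraph",
    "DesignMatrix",
    "VertexGLM",
    "GLMResult",
    "InferenceResult",
    "glm_fit",
    "tfce",
    "permutation_test",
    "fwe_across",
    "interaction_screen",
    "clinical_association",
    "depth_group_analysis",
]


# ---------------------------------------------------------------------------
# mesh connectivity for cluster statistics


class SurfaceGraph:
    """Vertex connectivity and per-vertex surface areas of one or more
    meshes (disconnected hemisphere blocks are concatenated)."""

    def __init__(self, meshes):
        if isinstance(meshes, CorticalMesh):
            meshes = [meshes]
        edges = []
        areas = []
        off = 0
        for m in meshes:
            edges.append(m.edges + off)
            areas.append(m.vertex_areas)
            off += m.n_vertices
        self.edges = np.vstack(edges)
        self.vertex_areas = np.concatenate(areas)
        self.n_vertices = off


# ---------------------------------------------------------------------------
# vertexwise GLM


@dataclass
class DesignMatrix:
    """Response and design for one modality at one depth (or gradient).

    ``vertex_nuisance`` entries are (n_subjects, n_vertices) maps entering
    Z as a per-vertex column (thickness, curvature).
    """

    Y: np.ndarray  # (n, v)
    X: np.ndarray  # (n,)
    Z: np.ndarray | None = None  # (n, k) global nuisance incl. intercept
    vertex_nuisance: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.X = np.asarray(self.X, dtype=float).ravel()
        n = len(self.X)
        if self.Y.shape[0] != n:
            raise ValueError("Y rows must match X length")
        if self.Z is None:
            self.Z = np.ones((n, 1))
        self.Z = np.asarray(self.Z, dtype=float)
        for name, m in self.vertex_nuisance.items():
            if np.asarray(m).shape != self.Y.shape:
                raise ValueError(f"vertexwise nuisance {name!r} must match Y shape")


class VertexGLM:
    """Precomputed per-vertex nuisance projections for fast permutation.

    By Frisch-Waugh-Lovell, the t-statistic of X in [X Z] equals the t of
    the Z-residualized X against the Z-residualized Y, so after
    precomputing the per-vertex hat matrices only a matrix-vector product
    per permutation is needed.
    """

    def __init__(self, design: DesignMatrix):
        Y, Z = design.Y, design.Z
        n, v = Y.shape
        extra = [np.asarray(m, dtype=float) for m in design.vertex_nuisance.values()]
        k = Z.shape[1] + len(extra)
        Zv = np.empty((v, n, k))
        Zv[:, :, : Z.shape[1]] = Z[None, :, :]
        for j, m in enumerate(extra):
            Zv[:, :, Z.shape[1] + j] = m.T
        G = np.einsum("vnk,vnl->vkl", Zv, Zv)
        Ginv = np.linalg.pinv(G)
        # hat matrices P_v = Z_v Ginv Z_v^T, (v, n, n)
        self.P = np.einsum("vnk,vkl,vml->vnm", Zv, Ginv, Zv)
        self.Zv = Zv
        self.Ginv = Ginv
        self.Yt = Y.T - np.einsum("vnm,vm->vn", self.P, Y.T)  # residualized Y
        self.n = n
        self.n_vertices = v
        self.df = n - k - 1
        if self.df < 1:
            raise ValueError("not enough subjects for the design")
        # rank check per vertex: nuisance must not absorb everything
        self.rank = np.linalg.matrix_rank(G)
        self.valid = np.ones(v, dtype=bool)

    def t_for(self, x: np.ndarray) -> np.ndarray:
        """t-statistic of the X coefficient at every vertex for regressor x."""
        xt = x[None, :] - np.einsum("vnm,m->vn", self.P, x)
        den = np.einsum("vn,vn->v", xt, xt)
        num = np.einsum("vn,vn->v", xt, self.Yt)
        ok = den > 1e-12 * float(x @ x + 1e-300)
        b = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
        rss = np.einsum("vn,vn->v", self.Yt, self.Yt) - b * num
        sigma2 = np.maximum(rss, 0.0) / self.df
        with np.errstate(invalid="ignore", divide="ignore"):
            t = b / np.sqrt(sigma2 / np.where(ok, den, 1.0))
        t[~ok] = 0.0
        t[~self.valid] = 0.0
        return np.nan_to_num(t)


@dataclass
class GLMResult:
    b: np.ndarray  # X coefficient per vertex
    g: np.ndarray  # nuisance coefficients, (v, k)
    t: np.ndarray
    valid: np.ndarray
    df: int


def glm_fit(design: DesignMatrix) -> GLMResult:
    """Ordinary least squares per vertex; t for the X coefficient.

    Rank-deficient vertices are flagged and excluded from cluster support.
    """
    Y, X, Z = design.Y, design.X, design.Z
    n, v = Y.shape
    extra = [np.asarray(m, dtype=float) for m in design.vertex_nuisance.values()]
    p = 1 + Z.shape[1] + len(extra)
    D = np.empty((v, n, p))
    D[:, :, 0] = X[None, :]
    D[:, :, 1 : 1 + Z.shape[1]] = Z[None, :, :]
    for j, m in enumerate(extra):
        D[:, :, 1 + Z.shape[1] + j] = m.T
    G = np.einsum("vnk,vnl->vkl", D, D)
    ranks = np.linalg.matrix_rank(G)
    valid = ranks == p
    Ginv = np.linalg.pinv(G)
    beta = np.einsum("vkl,vnl,vn->vk", Ginv, D, Y.T)
    resid = Y.T - np.einsum("vnk,vk->vn", D, beta)
    df = n - p
    sigma2 = np.einsum("vn,vn->v", resid, resid) / max(df, 1)
    var_b = Ginv[:, 0, 0] * sigma2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[:, 0] / np.sqrt(var_b)
    t = np.nan_to_num(t)
    t[~valid] = 0.0
    return GLMResult(b=beta[:, 0], g=beta[:, 1:], t=t, valid=valid, df=df)


# ---------------------------------------------------------------------------
# threshold-free cluster enhancement


def _tfce_one_sided(s: np.ndarray, graph: SurfaceGraph, E: float, H: float, dh: float):
    """TFCE of the positive part of ``s`` on a discrete threshold grid.

    TFCE(v) = sum over grid thresholds h of extent(v, h)^E h^H dh, where
    extent is the surface area of the suprathreshold connected component
    containing v.  Computed exactly in one sweep: events (vertex
    activations and edge unions) are processed in descending threshold
    order building the component merge tree; each tree node accumulates
    its constant-area contribution, pushed down to the leaves at the end.
    """
    out = np.zeros(graph.n_vertices)
    smax = float(np.max(s, initial=0.0))
    if smax <= 0 or dh <= 0:
        return out
    grid = np.arange(dh, smax + 0.5 * dh, dh)
    if len(grid) == 0:
        return out
    # prefix[i] = sum of h^H dh over grid[:i]
    prefix = np.concatenate([[0.0], np.cumsum(grid**H * dh)])

    def seg(lo: float, hi: float) -> float:
        # sum of h^H dh over grid thresholds in (lo, hi]
        return prefix[np.searchsorted(grid, hi, "right")] - prefix[
            np.searchsorted(grid, lo, "right")
        ]

    active_v = np.flatnonzero(s > 0)
    e = graph.edges
    emask = (s[e[:, 0]] > 0) & (s[e[:, 1]] > 0)
    e = e[emask]
    eval_ = np.minimum(s[e[:, 0]], s[e[:, 1]])
    v_order = active_v[np.argsort(-s[active_v], kind="stable")]
    e_order = np.argsort(-eval_, kind="stable")

    nv = graph.n_vertices
    max_nodes = 2 * nv
    parent = np.full(max_nodes, -1, dtype=np.int64)  # dendrogram parent
    root_of = {}  # current union-find root per vertex tree id is below
    uf = np.arange(max_nodes)
    area = np.zeros(max_nodes)
    birth = np.zeros(max_nodes)
    contrib = np.zeros(max_nodes)
    node_for = np.full(max_nodes, -1, dtype=np.int64)  # uf root -> tree node
    next_node = nv
    va = graph.vertex_areas

    def find(a):
        while uf[a] != a:
            uf[a] = uf[uf[a]]
            a = uf[a]
        return a

    vi = 0
    ei = 0
    n_v = len(v_order)
    n_e = len(e_order)
    order_nodes = []
    while vi < n_v or ei < n_e:
        if ei >= n_e or (vi < n_v and s[v_order[vi]] >= eval_[e_order[ei]]):
            v = int(v_order[vi])
            vi += 1
            area[v] = va[v]
            birth[v] = s[v]
            node_for[v] = v
            uf[v] = v
            order_nodes.append(v)
        else:
            ed = e[e_order[ei]]
            h = eval_[e_order[ei]]
            ei += 1
            ra, rb = find(int(ed[0])), find(int(ed[1]))
            if ra == rb:
                continue
            na, nb = node_for[ra], node_for[rb]
            contrib[na] += area[na] ** E * seg(h, birth[na])
            contrib[nb] += area[nb] ** E * seg(h, birth[nb])
            new = next_node
            next_node += 1
            parent[na] = new
            parent[nb] = new
            uf[rb] = ra
            node_for[ra] = new
            area[new] = area[na] + area[nb]
            birth[new] = h
            order_nodes.append(new)
    # close all surviving components down to the lowest threshold
    seen = set()
    for v in map(int, active_v):
        r = find(v)
        if r not in seen:
            seen.add(r)
            nd = node_for[r]
            contrib[nd] += area[nd] ** E * seg(0.0, birth[nd])
    # push contributions down the merge tree (parents created after children)
    for nd in reversed(order_nodes):
        if parent[nd] >= 0:
            contrib[nd] += contrib[parent[nd]]
    out[active_v] = contrib[active_v]
    return out


def tfce(
    stat_map: np.ndarray,
    graph: SurfaceGraph | CorticalMesh,
    E: float = 1.0,
    H: float = 2.0,
    dh: float | None = None,
    n_steps: int = 100,
) -> np.ndarray:
    """Signed TFCE enhancement of a vertexwise statistic map.

    Positive and negative tails are enhanced separately (the negative tail
    by applying the same integral to -stat) and recombined with sign.
    ``dh`` defaults to max|stat| / n_steps, one shared grid for both tails;
    extent is measured as component surface area (mm^2).
    """
    if isinstance(graph, CorticalMesh):
        graph = SurfaceGraph(graph)
    s = np.nan_to_num(np.asarray(stat_map, dtype=float))
    if s.shape != (graph.n_vertices,):
        raise ValueError("stat map length must match mesh vertex count")
    if dh is None:
        m = float(np.max(np.abs(s), initial=0.0))
        if m == 0.0:
            return np.zeros_like(s)
        dh = m / n_steps
    if dh <= 0:
        raise ValueError("dh must be positive")
    pos = _tfce_one_sided(np.maximum(s, 0.0), graph, E, H, dh)
    neg = _tfce_one_sided(np.maximum(-s, 0.0), graph, E, H, dh)
    return pos - neg


# ---------------------------------------------------------------------------
# permutation inference


@dataclass
class InferenceResult:
    """Observed maps and permutation p-values for one contrast.

    p-values use (1 + b) / (1 + m) counting for sampled schedules and the
    exact proportion over all distinct arrangements for exhaustive ones,
    so the minimum attainable p is 1/(1 + n_perm) and never 0.
    """

    t: np.ndarray
    tfce_map: np.ndarray  # signed enhancement
    stat_obs: np.ndarray  # contrast-directed statistic actually tested
    p_uncorrected: np.ndarray
    p_fwe: np.ndarray
    p_fwe_across: np.ndarray | None
    n_perm: int
    seed: int
    alternative: str
    exhaustive: bool
    perm_max: np.ndarray  # max statistic over vertices per permutation
    schedule_id: str
    valid: np.ndarray

    def check_monotone(self) -> None:
        if np.any(self.p_fwe + 1e-12 < self.p_uncorrected):
            raise AssertionError("FWE-within below uncorrected p")
        if self.p_fwe_across is not None and np.any(
            self.p_fwe_across + 1e-12 < self.p_fwe
        ):
            raise AssertionError("FWE-across below FWE-within")


def _count_distinct_arrangements(x: np.ndarray, cap: int) -> int:
    """Distinct row-orders of x (multiset permutations), clipped at cap."""
    _, counts = np.unique(x, return_counts=True)
    total = 1
    n = len(x)
    remaining = n
    for c in counts:
        # multiply binomial(remaining, c) incrementally, stop at cap
        from math import comb

        total *= comb(remaining, c)
        remaining -= c
        if total > cap:
            return cap + 1
    return total


def _permutation_schedule(x: np.ndarray, n_perm: int, seed: int):
    """Rows of the permuted-X matrix: observed first, then the nulls.

    Falls back to exhaustive enumeration of all distinct arrangements
    when the request covers them; otherwise draws distinct random
    row-orders without replacement.
    """
    n = len(x)
    n_distinct = _count_distinct_arrangements(x, max(n_perm, 10000))
    if n_distinct <= n_perm + 1:
        perms = np.array(list(multiset_permutations(list(x))), dtype=float)
        # put the observed arrangement first
        obs = np.flatnonzero((perms == x[None, :]).all(axis=1))[0]
        order = np.r_[obs, np.delete(np.arange(len(perms)), obs)]
        return perms[order], True
    rng = np.random.default_rng(seed)
    seen = {x.tobytes()}
    rows = [x]
    guard = 0
    while len(rows) < n_perm + 1 and guard < 50 * n_perm + 1000:
        cand = x[rng.permutation(n)]
        key = cand.tobytes()
        guard += 1
        if key in seen:
            continue
        seen.add(key)
        rows.append(cand)
    return np.asarray(rows), False


def _directed(enh: np.ndarray, alternative: str) -> np.ndarray:
    if alternative == "greater":
        return enh
    if alternative == "less":
        return -enh
    if alternative == "two-sided":
        return np.abs(enh)
    raise ValueError(f"unknown alternative {alternative!r}")


def _pvalues(stats: np.ndarray, obs: np.ndarray, exhaustive: bool):
    """Uncorrected and max-statistic FWE p-values from a permutation
    distribution whose first row is the observed arrangement."""
    perm_max = stats.max(axis=1)
    if exhaustive:
        p_unc = (stats >= obs[None, :] - 1e-12).mean(axis=0)
        p_fwe = (perm_max[:, None] >= obs[None, :] - 1e-12).mean(axis=0)
    else:
        m = len(stats) - 1
        p_unc = (1.0 + (stats[1:] >= obs[None, :] - 1e-12).sum(axis=0)) / (1.0 + m)
        p_fwe = (
            1.0 + (perm_max[1:, None] >= obs[None, :] - 1e-12).sum(axis=0)
        ) / (1.0 + m)
    return p_unc, p_fwe, perm_max


def _run_permutation_family(
    design: DesignMatrix,
    graph: SurfaceGraph,
    alternatives: tuple[str, ...],
    n_perm: int,
    seed: int,
    E: float,
    H: float,
    dh: float | None,
    n_steps: int,
) -> list[InferenceResult]:
    """One permutation sweep serving several contrast directions.

    The signed TFCE enhancement is computed once per permutation; each
    requested alternative reads its directed statistic off it (the two
    one-sided contrasts are sign mirrors), so all returned results share
    the permutation schedule exactly.
    """
    glm = VertexGLM(design)
    perms, exhaustive = _permutation_schedule(design.X, n_perm, seed)
    enh = np.empty((len(perms), glm.n_vertices))
    for i, xp in enumerate(perms):
        enh[i] = tfce(glm.t_for(xp), graph, E, H, dh, n_steps)
    t_obs = glm.t_for(design.X)
    sched = hashlib.sha256(perms.tobytes()).hexdigest()[:16]
    out = []
    for alt in alternatives:
        stats = _directed(enh, alt)
        obs = stats[0]
        p_unc, p_fwe, perm_max = _pvalues(stats, obs, exhaustive)
        out.append(
            InferenceResult(
                t=t_obs,
                tfce_map=enh[0].copy(),
                stat_obs=obs,
                p_uncorrected=p_unc,
                p_fwe=p_fwe,
                p_fwe_across=None,
                n_perm=len(perms) - 1,
                seed=seed,
                alternative=alt,
                exhaustive=exhaustive,
                perm_max=perm_max,
                schedule_id=sched,
                valid=glm.valid,
            )
        )
    return out


def permutation_test(
    design: DesignMatrix,
    graph: SurfaceGraph | CorticalMesh,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
    E: float = 1.0,
    H: float = 2.0,
    dh: float | None = None,
    n_steps: int = 100,
) -> InferenceResult:
    """Draper-Stoneman permutation inference with TFCE.

    The rows of X are permuted, Y and all nuisance columns stay fixed;
    per permutation the vertexwise t and its TFCE enhancement are
    recomputed.  Uncorrected p compares each vertex to its own null;
    FWE-within compares to the max-TFCE-over-vertices null.  Results with
    equal (X, seed, n_perm) share the permutation schedule and can be
    combined by :func:`fwe_across`.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(graph, CorticalMesh):
        graph = SurfaceGraph(graph)
    (res,) = _run_permutation_family(
        design, graph, (alternative,), n_perm, seed, E, H, dh, n_steps
    )
    return res


def fwe_across(results: list[InferenceResult]) -> list[InferenceResult]:
    """Joint FWE correction across modalities and contrasts.

    For each result the across-family p at a vertex is the proportion of
    permutations whose maximum statistic over *all* vertices, modalities
    and contrasts in the family reaches that vertex's observed statistic.
    All results must share the synchronized permutation schedule (same
    subject permutations, applied to every response).
    """
    if not results:
        return results
    n_perms = {r.n_perm for r in results}
    scheds = {(r.schedule_id, r.exhaustive) for r in results}
    if len(n_perms) != 1:
        raise ValueError("results must share n_perm")
    if len({s for s, _ in scheds}) != 1:
        raise ValueError("results must share the permutation schedule")
    family_max = np.max(np.stack([r.perm_max for r in results]), axis=0)
    for r in results:
        if r.exhaustive:
            p = (family_max[:, None] >= r.stat_obs[None, :] - 1e-12).sum(axis=0) / len(
                family_max
            )
        else:
            p = (
                1.0
                + (family_max[1:, None] >= r.stat_obs[None, :] - 1e-12).sum(axis=0)
            ) / (1.0 + r.n_perm)
        r.p_fwe_across = np.maximum(p, r.p_fwe)
        r.check_monotone()
    return results


# ---------------------------------------------------------------------------
# higher-level screens


def interaction_screen(
    Y: np.ndarray,
    group: np.ndarray,
    age: np.ndarray,
    Z: np.ndarray | None = None,
    vertex_nuisance: dict | None = None,
    graph=None,
    n_perm: int = 500,
    seed: int = 0,
    **tfce_kw,
) -> InferenceResult:
    """Age-by-group interaction test (both factors centered).

    X = centered(group) * centered(age); group, age and the intercept are
    nuisance.  Where this is not significant, downstream designs treat age
    and sex as covariates of no interest.
    """
    group = np.asarray(group, dtype=float)
    age = np.asarray(age, dtype=float)
    gc = group - group.mean()
    ac = age - age.mean()
    x = gc * ac
    n = len(x)
    zcols = [np.ones(n), gc, ac]
    if Z is not None:
        zcols += [np.asarray(Z, dtype=float).reshape(n, -1)[:, j] for j in
                  range(np.asarray(Z).reshape(n, -1).shape[1])]
    design = DesignMatrix(
        Y=Y, X=x, Z=np.column_stack(zcols), vertex_nuisance=vertex_nuisance or {}
    )
    return permutation_test(
        design, graph, n_perm=n_perm, seed=seed, alternative="two-sided", **tfce_kw
    )


def clinical_association(
    Y: np.ndarray,
    clinical_value: np.ndarray,
    Z: np.ndarray | None = None,
    transform: str = "log",
    vertex_nuisance: dict | None = None,
    graph=None,
    n_perm: int = 500,
    seed: int = 0,
    alternative: str = "two-sided",
    **tfce_kw,
) -> InferenceResult:
    """Association of vertexwise maps with a clinical variable (patients
    only).  Skewed counts such as seizures per year are log-transformed."""
    c = np.asarray(clinical_value, dtype=float)
    if transform == "log":
        if np.any(c <= 0):
            raise ValueError("log transform requires positive values")
        x = np.log(c)
    elif transform in (None, "none"):
        x = c
    else:
        raise ValueError(f"unknown transform {transform!r}")
    design = DesignMatrix(Y=Y, X=x, Z=Z, vertex_nuisance=vertex_nuisance or {})
    return permutation_test(
        design, graph, n_perm=n_perm, seed=seed, alternative=alternative, **tfce_kw
    )


def depth_group_analysis(
    feature_sets: dict[str, list],
    table,
    thickness: np.ndarray,
    curvature: np.ndarray,
    graph: SurfaceGraph,
    levels=None,
    n_perm: int = 500,
    seed: int = 0,
    include_gradient: bool = True,
    **tfce_kw,
) -> dict:
    """Group comparison at each depth and on the gradient, both contrasts
    and modalities, FWE-corrected within and across per analysis.

    Parameters
    ----------
    feature_sets
        modality -> list of (already laterality-flipped) DepthFeatureSet,
        ordered as the rows of ``table``.
    table
        cohort covariates with columns group, age, sex.
    thickness, curvature
        (n_subjects, n_vertices) stacked vertexwise nuisance maps.

    Returns
    -------
    dict keyed (level_or_"gradient", modality, contrast) -> InferenceResult;
    the across-family correction pools the two modalities and the two
    one-sided contrasts of each level separately.
    """
    group = (table["group"].values == "patient").astype(float)
    age = table["age"].values.astype(float)
    sex = (table["sex"].values == "M").astype(float)
    Z = np.column_stack([np.ones(len(group)), age - age.mean(), sex])
    vn = {"thickness": thickness, "curvature": curvature}
    modalities = list(feature_sets)
    if levels is None:
        levels = [l for l in feature_sets[modalities[0]][0].levels if l >= 0]
    keys: list = list(levels) + (["gradient"] if include_gradient else [])
    out = {}
    for key in keys:
        fam = []
        for mod in modalities:
            fs = feature_sets[mod]
            if key == "gradient":
                Y = np.vstack([f.stacked_gradient() for f in fs])
            else:
                Y = np.vstack([f.stacked(key) for f in fs])
            Y = np.nan_to_num(Y)
            design = DesignMatrix(Y=Y, X=group, Z=Z, vertex_nuisance=vn)
            pair = _run_permutation_family(
                design, graph, ("greater", "less"), n_perm, seed,
                tfce_kw.get("E", 1.0), tfce_kw.get("H", 2.0),
                tfce_kw.get("dh"), tfce_kw.get("n_steps", 100),
            )
            for alt, res in zip(("greater", "less"), pair):
                name = "patients>controls" if alt == "greater" else "controls>patients"
                out[(key, mod, name)] = res
                fam.append(res)
        fwe_across(fam)
    return out
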