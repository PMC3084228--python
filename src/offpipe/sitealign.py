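"""Sequence-order-independent binding-site alignment and EVD significance.

Two sites are compared by building a correspondence graph: one vertex per
residue pair (i in A, j in B) whose chemistry + geometric-potential weight
exceeds ``w_min``, with an edge between two vertices when the intra-site
C-alpha distances they imply agree within ``epsilon``. Any clique of this
graph is an injective, geometrically consistent partial matching; the aligner
returns the maximum-weight clique (exact branch-and-bound up to
``exact_limit`` vertices, greedy seed-and-extend with restarts beyond). The
similarity score is the clique's total pair weight; significance against a
background of decoy alignments follows a Gumbel (type-I extreme-value) model,
the classical null for best-of-many alignment scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from scipy import stats

from .errors import (
    FitError,
    ScreeningError,
    SubstitutionTableError,
)
from .geometry import kabsch
from .sitecore import BindingSite

_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class AlignParams:
    """Tunables of the order-independent aligner (defaults are the shipped
    configuration: reproducible and small enough for exact search in tests)."""

    w_min: float = 0.8
    epsilon: float = 1.5  # Angstrom tolerance on intra-site distances
    exact_limit: int = 30  # max correspondence vertices for exact search
    restarts: int = 32  # greedy best-of-k restarts
    seed: int = 0
    lam: float = 1.0  # weight of the GP term
    matrix: str = "BLOSUM62"


@dataclass
class AlignmentResult:
    pairs: list[tuple[tuple[str, int], tuple[str, int]]]
    score: float
    rotation: np.ndarray | None
    translation: np.ndarray | None
    rmsd: float | None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class EVDModel:
    """Gumbel location/scale for alignment-score significance."""

    mu: float
    beta: float

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise FitError(f"EVD scale must be > 0, got {self.beta}")


@dataclass
class ScreenHit:
    target_id: str
    score: float
    p_value: float
    tier: str  # "none" | "significant" | "stringent"


_MATRIX_CACHE: dict[str, object] = {}


def _get_matrix(name: str):
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = substitution_matrices.load(name)
    return _MATRIX_CACHE[name]


def residue_pair_similarity(
    res_a: tuple[str, float], res_b: tuple[str, float], params: AlignParams | None = None
) -> float:
    """Chemistry + environment weight for one candidate residue pair.

    ``res_a``/``res_b`` are (three-letter residue name, GP score) tuples;
    weight = S(a, b) / S_max + lam * (1 - |GP_a - GP_b| / 100), with S a
    symmetric substitution table (BLOSUM62 by default) and S_max its largest
    diagonal entry.
    """
    params = params or AlignParams()
    mat = _get_matrix(params.matrix)
    try:
        one_a = _3TO1[res_a[0].upper()]
        one_b = _3TO1[res_b[0].upper()]
        s = mat[one_a, one_b]
    except KeyError as exc:
        raise SubstitutionTableError(f"unknown residue code: {exc}") from exc
    s_max = max(mat[c, c] for c in _3TO1.values())
    return float(s / s_max + params.lam * (1.0 - abs(res_a[1] - res_b[1]) / 100.0))


def superpose_points(P: np.ndarray, Q: np.ndarray):
    """Optimal proper rotation + translation mapping Q onto P (least squares);
    returns ``(rotation, translation, rmsd)``."""
    return kabsch(P, Q)


# -- correspondence-graph construction and clique search --------------------

def _build_graph(A: BindingSite, B: BindingSite, params: AlignParams):
    verts: list[tuple[int, int]] = []
    weights: list[float] = []
    for i in range(len(A)):
        for j in range(len(B)):
            w = residue_pair_similarity(
                (A.residue_names[i], A.gp[i]), (B.residue_names[j], B.gp[j]), params
            )
            if w > params.w_min:
                verts.append((i, j))
                weights.append(w)
    nv = len(verts)
    dA = np.linalg.norm(A.ca_coords[:, None] - A.ca_coords[None, :], axis=2)
    dB = np.linalg.norm(B.ca_coords[:, None] - B.ca_coords[None, :], axis=2)
    adj = np.zeros((nv, nv), dtype=bool)
    for u in range(nv):
        iu, ju = verts[u]
        for v in range(u + 1, nv):
            iv, jv = verts[v]
            if iu != iv and ju != jv and abs(dA[iu, iv] - dB[ju, jv]) <= params.epsilon:
                adj[u, v] = adj[v, u] = True
    return verts, np.array(weights), adj


def _clique_exact(weights: np.ndarray, adj: np.ndarray) -> list[int]:
    """Branch-and-bound maximum-weight clique; deterministic tie-break by
    lexicographic vertex-index list."""
    nv = len(weights)
    order = sorted(range(nv), key=lambda v: (-weights[v], v))
    best: dict = {"score": 0.0, "set": []}

    def expand(cur: list[int], cur_w: float, cand: list[int]) -> None:
        if cur_w > best["score"] + 1e-12 or (
            abs(cur_w - best["score"]) <= 1e-12 and cur and sorted(cur) < best["set"]
        ):
            best["score"], best["set"] = cur_w, sorted(cur)
        bound = cur_w + sum(weights[v] for v in cand)
        if bound < best["score"] - 1e-12:
            return
        for k, v in enumerate(cand):
            rest = [u for u in cand[k + 1:] if adj[v, u]]
            if cur_w + weights[v] + sum(weights[u] for u in rest) < best["score"] - 1e-12:
                continue
            expand(cur + [v], cur_w + weights[v], rest)

    expand([], 0.0, order)
    return best["set"]


def _clique_greedy(weights: np.ndarray, adj: np.ndarray, params: AlignParams) -> list[int]:
    nv = len(weights)
    rng = np.random.default_rng(params.seed)
    seeds = list(np.argsort(-weights)[: params.restarts])
    while len(seeds) < params.restarts and nv:
        seeds.append(int(rng.integers(0, nv)))
    best_set: list[int] = []
    best_w = 0.0
    for s in seeds:
        clique = [int(s)]
        cand = [v for v in range(nv) if adj[s, v]]
        w = weights[s]
        while cand:
            v = max(cand, key=lambda u: (weights[u], -u))
            clique.append(v)
            w += weights[v]
            cand = [u for u in cand if u != v and adj[v, u]]
        if w > best_w + 1e-12 or (abs(w - best_w) <= 1e-12 and sorted(clique) < best_set):
            best_w, best_set = w, sorted(clique)
    return best_set


def align_sites(
    A: BindingSite, B: BindingSite, params: AlignParams | None = None
) -> AlignmentResult:
    """Maximum-weight geometrically consistent residue matching of two sites.

    Returns the matched residue pairs, the total pair weight as the
    similarity score, and (for >=3 pairs) the rigid transform mapping B's
    C-alphas onto A's with its RMSD.
    """
    params = params or AlignParams()
    if len(A) < 3 or len(B) < 3:
        raise ValueError("alignable sites need >= 3 residues")
    verts, weights, adj = _build_graph(A, B, params)
    if not verts:
        return AlignmentResult([], 0.0, None, None, None)
    if len(verts) <= params.exact_limit:
        clique = _clique_exact(weights, adj)
    else:
        clique = _clique_greedy(weights, adj, params)
    clique = sorted(clique, key=lambda v: verts[v])
    pairs = [(A.residue_ids[verts[v][0]], B.residue_ids[verts[v][1]]) for v in clique]
    score = float(sum(weights[v] for v in clique))
    rotation = translation = rmsd_val = None
    if len(clique) >= 3:
        pa = A.ca_coords[[verts[v][0] for v in clique]]
        pb = B.ca_coords[[verts[v][1] for v in clique]]
        try:
            rotation, translation, rmsd_val = kabsch(pa, pb)
        except Exception:
            pass  # collinear matches keep their score but carry no transform
    return AlignmentResult(pairs, score, rotation, translation, rmsd_val)


# -- extreme-value significance ---------------------------------------------

EULER_MASCHERONI = 0.5772156649015329


def fit_evd(background_scores) -> EVDModel:
    """Maximum-likelihood Gumbel fit, started from method-of-moments
    (beta = s * sqrt(6) / pi, mu = mean - 0.5772 * beta)."""
    x = np.asarray(background_scores, dtype=float)
    if x.size < 50:
        raise FitError(f"need >= 50 background scores, got {x.size}")
    s = x.std(ddof=1)
    if s < 1e-12:
        raise FitError("constant background scores: EVD undefined")
    beta0 = s * np.sqrt(6.0) / np.pi
    mu0 = x.mean() - EULER_MASCHERONI * beta0
    mu, beta = stats.gumbel_r.fit(x, loc=mu0, scale=beta0)
    return EVDModel(float(mu), float(beta))


def evd_pvalue(score: float, model: EVDModel) -> float:
    """Gumbel upper-tail probability ``1 - exp(-exp(-(s - mu) / beta))``,
    clamped to (1e-300, 1]."""
    z = (score - model.mu) / model.beta
    p = float(-np.expm1(-np.exp(-z)))
    return min(max(p, 1e-300), 1.0)


def _tier(p: float, alpha: float, alpha_stringent: float) -> str:
    if p < alpha_stringent:
        return "stringent"
    if p < alpha:
        return "significant"
    return "none"


def make_decoy_site(site: BindingSite, rng: np.random.Generator) -> BindingSite:
    """GP-preserving residue-label shuffle: geometry and scores untouched,
    chemistry signal destroyed."""
    perm = rng.permutation(len(site))
    return BindingSite(
        parent_id=site.parent_id + ":decoy",
        residue_ids=list(site.residue_ids),
        residue_names=[site.residue_names[k] for k in perm],
        ca_coords=site.ca_coords.copy(),
        gp=site.gp.copy(),
    )


def screen_sites(
    query: BindingSite,
    library: dict[str, BindingSite] | list[BindingSite],
    background=None,
    alpha: float = 1e-3,
    alpha_stringent: float = 1e-4,
    params: AlignParams | None = None,
    n_background: int = 200,
    seed: int = 0,
):
    """Align a query site against a site library and assign EVD p-values.

    ``background`` may be a precomputed score list; otherwise decoy
    backgrounds are generated by aligning the query to residue-label shuffles
    of the library sites. Returns ``(hits, background_scores)`` with hits
    sorted by ascending p-value.
    """
    params = params or AlignParams()
    if isinstance(library, list):
        library = {getattr(s, "parent_id", f"site{k}"): s for k, s in enumerate(library)}
    if not library:
        raise ScreeningError("empty site library")
    scores = {tid: align_sites(query, site, params).score for tid, site in library.items()}
    if background is None:
        rng = np.random.default_rng(seed)
        pool = list(library.values())
        bg = []
        for k in range(n_background):
            decoy = make_decoy_site(pool[k % len(pool)], rng)
            bg.append(align_sites(query, decoy, params).score)
        background = bg
    try:
        model = fit_evd(background)
    except FitError as exc:
        raise ScreeningError(f"background model failed: {exc}") from exc
    hits = [
        ScreenHit(tid, sc, evd_pvalue(sc, model), _tier(evd_pvalue(sc, model), alpha, alpha_stringent))
        for tid, sc in scores.items()
    ]
    hits.sort(key=lambda h: (h.p_value, -h.score, h.target_id))
    return hits, list(map(float, background))
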