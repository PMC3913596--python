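"""Distance phylogenetics with model selection, bootstrap, ELW and
clade-diagnostic sites.

Tree topology estimation is neighbour joining on model-corrected
distances (JC69, K80, TN93 in closed form; HKY85 uses the TN93
distance).  Model choice is by BIC/AIC with likelihoods computed by the
pruning algorithm on a fixed NJ starting topology, with 4-category
discrete-gamma rate heterogeneity.  Topologies are compared with
expected likelihood weights over RELL resamples of the site
log-likelihood vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .seq_model import Alignment

NUCS = "ACGT"
_NUC_IDX = {b: i for i, b in enumerate(NUCS)}
MODEL_NAMES = ("JC69", "K80", "HKY85", "TN93")


@dataclass(frozen=True)
class SubstitutionModel:
    name: str
    kappa: float = 1.0             # ts/tv rate ratio (K80/HKY85)
    kappa1: float = 1.0            # A<->G rate multiplier (TN93)
    kappa2: float = 1.0            # C<->T rate multiplier (TN93)
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma_alpha: float | None = None

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")
        if not math.isclose(sum(self.base_frequencies), 1.0, abs_tol=1e-6):
            raise ValueError("base frequencies must sum to 1")
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma_alpha must be > 0")

    @property
    def n_free_parameters(self) -> int:
        k = {"JC69": 0, "K80": 1, "HKY85": 1, "TN93": 2}[self.name]
        if self.name in ("HKY85", "TN93"):
            k += 3  # empirical base frequencies
        if self.gamma_alpha is not None:
            k += 1
        return k

    def rate_matrix(self) -> np.ndarray:
        """4x4 rate matrix (ACGT order) normalised to 1 expected
        substitution per site per unit time."""
        pi = np.array(self.base_frequencies)
        if self.name in ("JC69", "K80"):
            pi = np.full(4, 0.25)
        if self.name == "TN93":
            a1, a2, b = self.kappa1, self.kappa2, 1.0
        else:
            a1 = a2 = self.kappa if self.name != "JC69" else 1.0
            b = 1.0
        q = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                pair = {i, j}
                if pair == {0, 2}:       # A<->G
                    rate = a1
                elif pair == {1, 3}:     # C<->T
                    rate = a2
                else:
                    rate = b
                q[i, j] = rate * pi[j]
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -float(np.dot(pi, np.diag(q)))
        return q / scale


def transition_matrix(model: SubstitutionModel, t: float,
                      rate: float = 1.0) -> np.ndarray:
    q = model.rate_matrix() * rate
    pi = np.array(model.base_frequencies)
    if model.name in ("JC69", "K80"):
        pi = np.full(4, 0.25)
    # reversible Q: symmetrise with pi^1/2 for a stable eigendecomposition
    s = np.sqrt(pi)
    sym = (q * s[:, None]) / s[None, :]
    w, v = np.linalg.eigh((sym + sym.T) / 2)
    p = (v * np.exp(w * t)) @ v.T
    p = p * (s[None, :] / s[:, None])
    np.clip(p, 1e-300, None, out=p)
    return p / p.sum(axis=1, keepdims=True)


def gamma_category_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean rates of k equiprobable discrete-gamma categories (mean 1)."""
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
    edges[0], edges[-1] = 0.0, np.inf
    upper = gammainc(alpha + 1, np.where(np.isinf(edges), np.inf, edges * alpha)[1:])
    lower = gammainc(alpha + 1, edges[:-1] * alpha)
    return k * (upper - lower)


# ---------------------------------------------------------------------------
# pairwise distances


def _pair_proportions(a: str, b: str) -> tuple[float, float, float, int]:
    """(P1, P2, Q, n) = A<->G, C<->T transition and transversion
    proportions over jointly ungapped, unambiguous columns."""
    p1 = p2 = q = n = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in _NUC_IDX or y not in _NUC_IDX:
            continue
        n += 1
        if x == y:
            continue
        pair = {x, y}
        if pair == {"A", "G"}:
            p1 += 1
        elif pair == {"C", "T"}:
            p2 += 1
        else:
            q += 1
    if n == 0:
        raise ValueError("no comparable columns")
    return p1 / n, p2 / n, q / n, n


def _log_or_gamma(w: float, weight: float, alpha: float | None) -> float:
    """Contribution -weight*ln(w), or its gamma-corrected analogue."""
    if w <= 0:
        return float("nan")
    if alpha is None:
        return -weight * math.log(w)
    return weight * alpha * (w ** (-1.0 / alpha) - 1.0)


def model_distance(a: str, b: str, model: SubstitutionModel) -> float:
    """Model-corrected distance between two aligned sequences.

    Saturated pairs (non-positive logarithm argument) give NaN.
    """
    p1, p2, q, _ = _pair_proportions(a, b)
    alpha = model.gamma_alpha
    if model.name == "JC69":
        p = p1 + p2 + q
        return _log_or_gamma(1.0 - 4.0 * p / 3.0, 0.75, alpha)
    if model.name == "K80":
        p = p1 + p2
        d1 = _log_or_gamma(1.0 - 2.0 * p - q, 0.5, alpha)
        d2 = _log_or_gamma(1.0 - 2.0 * q, 0.25, alpha)
        return d1 + d2
    # TN93 (also used for HKY85)
    pi = np.array(model.base_frequencies)
    gA, gC, gG, gT = pi
    gR, gY = gA + gG, gC + gT
    if min(gR, gY) <= 0:
        return float("nan")
    k1 = 2.0 * gA * gG / gR
    k2 = 2.0 * gT * gC / gY
    k3 = 2.0 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
    w1 = 1.0 - p1 / k1 - q / (2.0 * gR) if k1 > 0 else 1.0
    w2 = 1.0 - p2 / k2 - q / (2.0 * gY) if k2 > 0 else 1.0
    w3 = 1.0 - q / (2.0 * gR * gY)
    total = 0.0
    for w, weight in ((w1, k1), (w2, k2), (w3, k3)):
        if weight <= 0:
            continue
        contrib = _log_or_gamma(w, weight, alpha)
        total += contrib
    return total


def empirical_frequencies(aln: Alignment) -> tuple[float, float, float, float]:
    counts = np.zeros(4)
    for _, seq in aln.records:
        for ch in seq.upper():
            if ch in _NUC_IDX:
                counts[_NUC_IDX[ch]] += 1
    if counts.sum() == 0:
        return (0.25, 0.25, 0.25, 0.25)
    return tuple(counts / counts.sum())


def distance_matrix(aln: Alignment, model: SubstitutionModel) -> np.ndarray:
    """Symmetric model-corrected distance matrix; NaN marks saturation."""
    n = len(aln)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = model_distance(aln.records[i][1], aln.records[j][1], model)
            out[i, j] = out[j, i] = d
    return out


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    name: str | None = None
    children: list = field(default_factory=list)   # [(TreeNode, branch_length)]

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return self.name
        parts = [f"{c._newick_inner()}:{bl:.10g}" for c, bl in self.children]
        return "(" + ",".join(parts) + ")"


@dataclass
class TreeResult:
    tree: TreeNode
    newick: str
    model: SubstitutionModel | None = None
    support: dict = field(default_factory=dict)   # bipartition -> percent


def nj_tree(dist: np.ndarray, names: list[str]) -> TreeResult:
    """Canonical neighbour joining; ties broken on lowest (row, col).

    Recovers topology and branch lengths exactly from additive matrices.
    """
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains missing values")
    n = len(names)
    if n < 2:
        raise ValueError("need >= 2 taxa")
    nodes = [TreeNode(name=nm) for nm in names]
    d = dist.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        qmat = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(qmat, np.inf)
        best = np.unravel_index(np.argmin(qmat), qmat.shape)
        i_loc, j_loc = min(best), max(best)
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        d = np.column_stack([d, np.append(new_row, 0.0)])
        nodes.append(parent)
        new_idx = d.shape[0] - 1
        active = [a for a in active if a not in (i, j)] + [new_idx]
        # keep insertion order stable for deterministic tie-breaking
    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
        lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
        lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
        root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    else:
        a, b = active
        root = TreeNode(children=[(nodes[a], d[a, b] / 2), (nodes[b], d[a, b] / 2)])
    return TreeResult(tree=root, newick=root.newick())


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial splits, each canonicalised as the side NOT containing
    the alphabetically first leaf."""
    all_leaves = sorted(tree.leaves())
    ref = all_leaves[0]
    full = set(all_leaves)
    out = set()

    def visit(node: TreeNode) -> set:
        if node.is_leaf:
            return {node.name}
        below = set()
        for child, _ in node.children:
            below |= visit(child)
        if 1 < len(below) < len(full) - 1:
            side = below if ref not in below else full - below
            out.add(frozenset(side))
        return below

    visit(tree)
    return out


def parse_newick(text: str) -> TreeNode:
    """Minimal Newick parser (names, branch lengths, no comments)."""
    s = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> tuple[TreeNode, float]:
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                child, bl = parse_node()
                node.children.append((child, bl))
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        start = pos
        while pos < len(s) and s[pos] not in ":,()":
            pos += 1
        label = s[start:pos]
        if label and node.is_leaf:
            node.name = label
        bl = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()":
                pos += 1
            bl = float(s[start:pos])
        return node, bl

    node, _ = parse_node()
    return node


# ---------------------------------------------------------------------------
# pruning likelihood


def _encode_alignment(aln: Alignment) -> dict[str, np.ndarray]:
    """Leaf partials: (n_sites, 4) indicators; gaps/ambiguity = all ones."""
    out = {}
    for name, seq in aln.records:
        arr = np.ones((len(seq), 4))
        for k, ch in enumerate(seq.upper()):
            if ch in _NUC_IDX:
                arr[k] = 0.0
                arr[k, _NUC_IDX[ch]] = 1.0
        out[name] = arr
    return out


def site_log_likelihoods(tree: TreeNode, aln: Alignment,
                         model: SubstitutionModel,
                         branch_scale: float = 1.0,
                         n_categories: int = 4) -> np.ndarray:
    """Per-site log-likelihoods by the pruning algorithm.

    Rate heterogeneity uses ``n_categories`` equiprobable discrete-gamma
    categories when the model carries a gamma_alpha.
    """
    leaf_partials = _encode_alignment(aln)
    missing = set(tree.leaves()) - set(aln.names)
    if missing:
        raise ValueError(f"tree leaves missing from alignment: {sorted(missing)}")
    pi = np.array(model.base_frequencies)
    if model.name in ("JC69", "K80"):
        pi = np.full(4, 0.25)
    rates = (gamma_category_rates(model.gamma_alpha, n_categories)
             if model.gamma_alpha is not None else np.array([1.0]))
    n_sites = aln.n_sites
    site_lik = np.zeros(n_sites)
    for rate in rates:
        def partial(node: TreeNode) -> np.ndarray:
            if node.is_leaf:
                return leaf_partials[node.name]
            result = np.ones((n_sites, 4))
            for child, bl in node.children:
                p = transition_matrix(model, max(bl, 0.0) * branch_scale, rate)
                result *= partial(child) @ p.T
            return result

        site_lik += (partial(tree) @ pi) / len(rates)
    return np.log(np.clip(site_lik, 1e-300, None))


def log_likelihood(tree: TreeNode, aln: Alignment, model: SubstitutionModel,
                   branch_scale: float = 1.0) -> float:
    return float(site_log_likelihoods(tree, aln, model, branch_scale).sum())


# ---------------------------------------------------------------------------
# model selection


def _fit_model(name: str, tree: TreeNode, aln: Alignment,
               freqs: tuple, with_gamma: bool) -> tuple[SubstitutionModel, float, float]:
    """Optimise substitution parameters + branch scale (+ alpha) for one
    model family on the fixed starting topology."""

    def build(theta: np.ndarray) -> tuple[SubstitutionModel, float]:
        i = 0
        kwargs: dict = {"name": name}
        if name in ("K80", "HKY85"):
            kwargs["kappa"] = math.exp(theta[i]); i += 1
        elif name == "TN93":
            kwargs["kappa1"] = math.exp(theta[i]); i += 1
            kwargs["kappa2"] = math.exp(theta[i]); i += 1
        if name in ("HKY85", "TN93"):
            kwargs["base_frequencies"] = freqs
        if with_gamma:
            kwargs["gamma_alpha"] = min(math.exp(theta[i]), 100.0); i += 1
        scale = math.exp(theta[i])
        return SubstitutionModel(**kwargs), scale

    n_subst = {"JC69": 0, "K80": 1, "HKY85": 1, "TN93": 2}[name]
    x0 = [math.log(2.0)] * n_subst + ([math.log(1.0 + 1e-9)] if with_gamma else []) + [0.0]

    def negloglik(theta: np.ndarray) -> float:
        model, scale = build(np.asarray(theta))
        try:
            return -log_likelihood(tree, aln, model, branch_scale=scale)
        except (ValueError, FloatingPointError):
            return 1e12

    res = minimize(negloglik, x0, method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 400})
    model, scale = build(res.x)
    return model, -res.fun, scale


def model_select(aln: Alignment,
                 candidates: tuple[str, ...] = MODEL_NAMES,
                 with_gamma: bool = True):
    """Choose a substitution model by BIC (AIC reported alongside).

    Likelihoods are computed on a fixed JC-distance NJ starting topology.
    Returns (best SubstitutionModel, table) where table rows carry name,
    lnL, k, BIC, AIC, gamma_alpha.
    """
    if len(aln) < 4:
        raise ValueError("model_select needs >= 4 sequences")
    p = distance_matrix(aln, SubstitutionModel(name="JC69"))
    if np.isnan(p).any():
        p = np.where(np.isnan(p), np.nanmax(p) * 2 if not np.isnan(p).all() else 1.0, p)
    start = nj_tree(p, aln.names).tree
    freqs = empirical_frequencies(aln)
    n_sites = aln.n_sites
    table = []
    for name in candidates:
        model, lnl, scale = _fit_model(name, start, aln, freqs, with_gamma)
        k = model.n_free_parameters
        table.append({
            "model": name, "lnL": lnl, "k": k,
            "BIC": -2 * lnl + k * math.log(max(n_sites, 1)),
            "AIC": -2 * lnl + 2 * k,
            "gamma_alpha": model.gamma_alpha,
            "fitted": model, "branch_scale": scale,
        })
    best = min(table, key=lambda row: (row["BIC"], MODEL_NAMES.index(row["model"])))
    return best["fitted"], table


# ---------------------------------------------------------------------------
# bootstrap and topology comparison


def build_tree(aln: Alignment, model: SubstitutionModel) -> TreeResult:
    d = distance_matrix(aln, model)
    if np.isnan(d).any():
        raise ValueError("saturated pairs in distance matrix")
    result = nj_tree(d, aln.names)
    result.model = model
    return result


def bootstrap_support(aln: Alignment, model: SubstitutionModel,
                      reps: int = 10_000, seed: int = 0) -> TreeResult:
    """Nonparametric bootstrap over alignment columns; support is the
    percentage of replicate NJ trees containing each original split."""
    base = build_tree(aln, model)
    target = bipartitions(base.tree)
    counts = dict.fromkeys(target, 0)
    rng = np.random.default_rng(seed)
    n_sites = aln.n_sites
    attempted = 0
    for _ in range(reps):
        cols = rng.integers(0, n_sites, size=n_sites)
        records = [(nm, "".join(seq[c] for c in cols)) for nm, seq in aln.records]
        rep_aln = Alignment(records, kind=aln.kind)
        try:
            d = distance_matrix(rep_aln, model)
            if np.isnan(d).any():
                continue
            rep_tree = nj_tree(d, rep_aln.names).tree
        except ValueError:
            continue
        attempted += 1
        rep_splits = bipartitions(rep_tree)
        for split in target:
            if split in rep_splits:
                counts[split] += 1
    denom = max(attempted, 1)
    base.support = {split: 100.0 * c / denom for split, c in counts.items()}
    return base


def elw_compare(aln: Alignment, model: SubstitutionModel,
                tree_a: TreeNode, tree_b: TreeNode,
                rell_reps: int = 10_000, seed: int = 0,
                confidence: float = 0.95) -> dict:
    """Expected likelihood weights of two topologies via RELL resampling.

    Returns weights (summing to 1) and membership of the 95% confidence
    tree set (greedy cumulative inclusion of the highest weights).
    """
    if set(tree_a.leaves()) != set(tree_b.leaves()):
        raise ValueError("trees must share one leaf set")
    ll_a = site_log_likelihoods(tree_a, aln, model)
    ll_b = site_log_likelihoods(tree_b, aln, model)
    rng = np.random.default_rng(seed)
    n_sites = len(ll_a)
    idx = rng.integers(0, n_sites, size=(rell_reps, n_sites))
    sum_a = ll_a[idx].sum(axis=1)
    sum_b = ll_b[idx].sum(axis=1)
    m = np.maximum(sum_a, sum_b)
    wa = np.exp(sum_a - m)
    wb = np.exp(sum_b - m)
    weights_a = wa / (wa + wb)
    w_a = float(weights_a.mean())
    w_b = 1.0 - w_a
    ordered = sorted([("tree_a", w_a), ("tree_b", w_b)], key=lambda x: -x[1])
    in_set, cum = set(), 0.0
    for name, w in ordered:
        in_set.add(name)
        cum += w
        if cum >= confidence:
            break
    return {"weight_a": w_a, "weight_b": w_b,
            "confidence_set": in_set,
            "both_in_confidence_set": in_set == {"tree_a", "tree_b"}}


def diagnostic_fixed_differences(aln: Alignment,
                                 clades: dict[str, str]) -> list[int]:
    """1-based columns where the residue sets of two clades are disjoint.

    ``clades`` maps sequence name -> clade label (exactly two labels);
    gap/ambiguity characters are excluded before comparing.
    """
    labels = sorted(set(clades.values()))
    if len(labels) != 2:
        raise ValueError("exactly two clades required")
    missing = set(aln.names) - set(clades)
    if missing:
        raise ValueError(f"sequences without clade assignment: {sorted(missing)}")
    groups = {lab: [nm for nm in aln.names if clades[nm] == lab] for lab in labels}
    for lab, members in groups.items():
        if len(members) == 1:
            import warnings
            warnings.warn(f"clade {lab!r} has a single sequence")
    out = []
    for pos in range(1, aln.n_sites + 1):
        sets = []
        for lab in labels:
            residues = {aln.sequence(nm)[pos - 1].upper() for nm in groups[lab]}
            residues -= set("-NX?")
            sets.append(residues)
        if sets[0] and sets[1] and not (sets[0] & sets[1]):
            out.append(pos)
    return out
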