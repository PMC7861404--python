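"""Independent oracles used by the test suite.

Everything here is deliberately written without reference to the package's
own estimator code paths: a dense multi-shell 21-parameter linear
least-squares DKI fit, a breadth-first flood-fill component labeler, and a
direct-formula Kruskal-Wallis / Dunn implementation.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

from fastdki.dki import MD_UNIT, KurtosisTissueModel

# ---------------------------------------------------------------- tensors ---

_SYM_PERMS = list(permutations(range(4)))


def fully_symmetrize(t: np.ndarray) -> np.ndarray:
    """Symmetrize the trailing four axes (leading axes are batch dims)."""
    lead = tuple(range(t.ndim - 4))
    out = np.zeros_like(t)
    for p in _SYM_PERMS:
        out += np.transpose(t, lead + tuple(t.ndim - 4 + i for i in p))
    return out / len(_SYM_PERMS)


def random_kurtosis_model(rng: np.random.Generator,
                          aniso: float = 0.3) -> KurtosisTissueModel:
    """Random positive-definite D (~1e-3 mm^2/s scale) + symmetric W."""
    a = rng.standard_normal((3, 3)) * aniso
    d = a @ a.T / 3.0 + np.eye(3) * rng.uniform(0.5, 1.2)
    w = fully_symmetrize(rng.standard_normal((3, 3, 3, 3))) * rng.uniform(0.1, 0.5)
    return KurtosisTissueModel(D=d, W=w)


# ------------------------------------------------- dense 21-parameter fit ---

def _design_row(b, n, md_placeholder=1.0):
    """ln S = -(b') D:nn + (1/6) b'^2 X:nnnn with b' = b*1e-3, X = MD^2 W."""
    bp = b * MD_UNIT
    dd = -bp * np.array([n[0] ** 2, n[1] ** 2, n[2] ** 2,
                         2 * n[0] * n[1], 2 * n[0] * n[2], 2 * n[1] * n[2]])
    quart = []
    from itertools import combinations_with_replacement
    for idx in combinations_with_replacement(range(3), 4):
        # multiplicity of each distinct 4-index combination
        mult = len({p for p in permutations(idx)})
        quart.append(mult * np.prod([n[i] for i in idx]))
    ww = (bp ** 2 / 6.0) * np.array(quart)
    return np.concatenate([dd, ww])


def dense_dki_design(rng: np.random.Generator, n_dirs: int = 60,
                     shells=(800.0, 1600.0, 2500.0)):
    """Fixed dense acquisition: n_dirs random unit vectors on each shell."""
    v = rng.standard_normal((n_dirs, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    rows, bvals, dirs = [], [], []
    for b in shells:
        for n in v:
            rows.append(_design_row(b, n))
            bvals.append(b)
            dirs.append(n)
    return np.array(rows), np.array(bvals), np.array(dirs)


def dense_oracle_fit(model: KurtosisTissueModel, design, bvals, dirs):
    """Fit all 21 DKI parameters by linear least squares on noise-free
    dense-acquisition log-signals; return (MD, MKT)."""
    lns = []
    for b, n in zip(bvals, dirs):
        bp = b * MD_UNIT
        dn = float(n @ model.D @ n)
        wn = float(np.einsum("ijlm,i,j,l,m->", model.W, n, n, n, n))
        lns.append(-bp * dn + (bp * model.md) ** 2 * wn / 6.0)
    coef, *_ = np.linalg.lstsq(design, np.array(lns), rcond=None)
    d6 = coef[:6]
    md = (d6[0] + d6[1] + d6[2]) / 3.0
    x15 = coef[6:]
    # tr(X) = X_xxxx + X_yyyy + X_zzzz + 2(X_xxyy + X_xxzz + X_yyzz)
    from itertools import combinations_with_replacement
    idx = list(combinations_with_replacement(range(3), 4))
    comp = dict(zip(idx, x15))
    tr_x = (comp[(0, 0, 0, 0)] + comp[(1, 1, 1, 1)] + comp[(2, 2, 2, 2)]
            + 2 * comp[(0, 0, 1, 1)] + 2 * comp[(0, 0, 2, 2)] + 2 * comp[(1, 1, 2, 2)])
    mkt = tr_x / (5.0 * md ** 2)
    return md, mkt


# ------------------------------------------------------------- flood fill ---

def flood_fill_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """BFS 26-connectivity labeling, independent of scipy.ndimage."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, int)
    offsets = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
               for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    current = 0
    for seed in zip(*np.nonzero(mask)):
        if labels[seed]:
            continue
        current += 1
        stack = [seed]
        labels[seed] = current
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= p[i] < mask.shape[i] for i in range(3)) \
                        and mask[p] and not labels[p]:
                    labels[p] = current
                    stack.append(p)
    return labels, current


# ----------------------------------------------------------- rank oracles ---

def midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), float)
    i = 0
    sv = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def brute_kruskal_h(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H from the textbook formula with tie correction."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = midranks(pooled)
    start, ssq = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        ssq += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * ssq - 3.0 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie


def brute_dunn_z(groups: list[np.ndarray], i: int, j: int) -> float:
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = midranks(pooled)
    means, sizes, start = [], [], 0
    for g in groups:
        means.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts ** 3 - counts)
    var = (n * (n + 1) / 12.0 - tie / (12.0 * (n - 1)))
    se = np.sqrt(var * (1.0 / sizes[i] + 1.0 / sizes[j]))
    return (means[i] - means[j]) / se


def group_relabelings(sizes: tuple[int, ...]):
    """All distinct assignments of indices 0..N-1 into groups of the given
    sizes (exhaustive permutation distribution)."""
    from itertools import combinations

    n = sum(sizes)

    def rec(remaining, szs):
        if not szs:
            yield ()
            return
        k = szs[0]
        for pick in combinations(remaining, k):
            rest = tuple(x for x in remaining if x not in pick)
            for tail in rec(rest, szs[1:]):
                yield (pick,) + tail

    yield from rec(tuple(range(n)), tuple(sizes))


# ---------------------------------------------- multinomial-logit simulator --

def simulate_multinomial_lesions(n: int, rng: np.random.Generator,
                                 beta_bh_mk: float,
                                 beta_cel_mk: float = 1.6,
                                 n_patients: int = 37):
    """Draw lesions from a 3-category multinomial logit (FLAIR-L reference).

    Intercepts are set for a class imbalance resembling an MS lesion cohort
    (few CE-L, FLAIR-L and BH dominating).  Returns a lesion-table-shaped
    DataFrame with a patient clustering column.
    """
    import pandas as pd

    mk = rng.normal(0.6, 0.13, n)
    eta = np.column_stack([
        np.zeros(n),                       # FLAIR-L (reference)
        -4.3 + beta_cel_mk * mk,           # CE-L
        0.77 + beta_bh_mk * mk,            # BH
    ])
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cat_idx = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    cats = np.array(["FLAIR-L", "CE-L", "BH"])[cat_idx]
    return pd.DataFrame({
        "category": cats,
        "mean_mkt": mk,
        "patient_id": (np.arange(n) % n_patients).astype(str),
    })
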