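"""Compiled (numba) kernels for graph mutation, change statistics and
Metropolis-Hastings proposals.

The Python-level :class:`~ergmee.graph.DirectedGraph` and
:func:`~ergmee.effects.change_stat` are the reference implementations; the
kernels here mirror them on flat arrays and numba typed containers so that
chains of 10^7+ proposals run at native speed.  Equality of the two
implementations is asserted in the test suite.

State layout (``GState`` namedtuple):

* ``n``            number of nodes
* ``meta``         int64[1]; ``meta[0]`` is the current arc count
* ``arc_set``      dict  i*n+j -> index into the flat arc arrays
* ``tails/heads``  preallocated int64 arrays (flat arc list, swap-delete)
* ``out_adj/in_adj`` typed list of typed int64 lists
* ``mix2``         dict  i*n+j -> # directed two-paths i->h->j
* ``in2``/``out2`` dicts keyed on sorted pairs: common predecessor /
                   successor counts; zero-count entries are deleted

Model layout (``CModel``): per-effect integer codes (the order of
``effects.EFFECT_NAMES``), damping lambdas, attribute row indices, and
attribute matrices (binary/continuous float64 with NaN for missing,
categorical int64 with -1 for missing).
"""

from __future__ import annotations

from collections import namedtuple

import numpy as np
from numba import njit, types
from numba.typed import Dict, List

from .graph import AttributeSet, DirectedGraph
from .effects import ATTR_KIND, ModelSpec

I64 = types.int64

GState = namedtuple("GState", "n meta arc_set tails heads out_adj in_adj mix2 in2 out2")
CModel = namedtuple("CModel", "codes lambdas attr_idx battrs cattrs uattrs")

# effect codes; must match effects.EFFECT_NAMES order
(ARC, RECIP, AINS, AOUTS, ATT, ATC, AKTD, AKTU,
 A2PT, A2PD, A2PTD, A2PU, ISOL,
 SENDER, RECEIVER, INTER,
 MATCH, MISMATCH, MATCHR, MISMATCHR,
 CSENDER, CRECEIVER, CDIFF) = range(23)


# ---------------------------------------------------------------------------
# state construction / extraction
# ---------------------------------------------------------------------------

@njit(cache=True)
def _empty_state(n, cap):
    arc_set = Dict.empty(I64, I64)
    mix2 = Dict.empty(I64, I64)
    in2 = Dict.empty(I64, I64)
    out2 = Dict.empty(I64, I64)
    out_adj = List()
    in_adj = List()
    for _ in range(n):
        out_adj.append(List.empty_list(I64))
        in_adj.append(List.empty_list(I64))
    return GState(n, np.zeros(1, np.int64),
                  arc_set, np.empty(cap, np.int64), np.empty(cap, np.int64),
                  out_adj, in_adj, mix2, in2, out2)


@njit(cache=True)
def _inc(d, key, delta):
    c = d.get(key, 0) + delta
    if c == 0:
        if key in d:
            d.pop(key)
    else:
        d[key] = c


@njit(cache=True)
def _adj_remove(lst, x):
    m = len(lst)
    for k in range(m):
        if lst[k] == x:
            lst[k] = lst[m - 1]
            lst.pop()
            return


@njit(cache=True)
def _add_arc(st, i, j):
    n = st.n
    m = st.meta[0]
    if m >= len(st.tails):
        raise RuntimeError("arc capacity exceeded; pass a larger arc_capacity")
    for h in st.out_adj[j]:
        if h != i:
            _inc(st.mix2, i * n + h, 1)
    for h in st.in_adj[i]:
        if h != j:
            _inc(st.mix2, h * n + j, 1)
    for h in st.out_adj[i]:
        _inc(st.in2, j * n + h if j < h else h * n + j, 1)
    for h in st.in_adj[j]:
        _inc(st.out2, i * n + h if i < h else h * n + i, 1)
    st.arc_set[i * n + j] = m
    st.tails[m] = i
    st.heads[m] = j
    st.meta[0] = m + 1
    st.out_adj[i].append(j)
    st.in_adj[j].append(i)


@njit(cache=True)
def _del_arc(st, i, j):
    n = st.n
    key = i * n + j
    pos = st.arc_set[key]
    st.arc_set.pop(key)
    m = st.meta[0] - 1
    if pos < m:
        ti = st.tails[m]
        hj = st.heads[m]
        st.tails[pos] = ti
        st.heads[pos] = hj
        st.arc_set[ti * n + hj] = pos
    st.meta[0] = m
    _adj_remove(st.out_adj[i], j)
    _adj_remove(st.in_adj[j], i)
    for h in st.out_adj[j]:
        if h != i:
            _inc(st.mix2, i * n + h, -1)
    for h in st.in_adj[i]:
        if h != j:
            _inc(st.mix2, h * n + j, -1)
    for h in st.out_adj[i]:
        _inc(st.in2, j * n + h if j < h else h * n + j, -1)
    for h in st.in_adj[j]:
        _inc(st.out2, i * n + h if i < h else h * n + i, -1)


@njit(cache=True)
def _fill_state(st, tails0, heads0):
    for k in range(len(tails0)):
        _add_arc(st, tails0[k], heads0[k])


@njit(cache=True)
def _reset_state(st, tails0, heads0):
    """Remove all arcs, then add the given ones (chain restart)."""
    while st.meta[0] > 0:
        m = st.meta[0]
        _del_arc(st, st.tails[m - 1], st.heads[m - 1])
    _fill_state(st, tails0, heads0)


# ---------------------------------------------------------------------------
# change statistics for adding arc (i, j) (arc must be absent)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _d_a2pt(st, lam, i, j):
    n = st.n
    r = 1.0 - 1.0 / lam
    d = 0.0
    for h in st.out_adj[j]:
        if h != i and i < h:
            d += r ** st.mix2.get(i * n + h, 0)
    for h in st.in_adj[i]:
        if h != j and h < j:
            d += r ** st.mix2.get(h * n + j, 0)
    return d


@njit(cache=True)
def _d_a2pd(st, lam, i, j):
    n = st.n
    r = 1.0 - 1.0 / lam
    d = 0.0
    for h in st.out_adj[i]:
        if h != j:
            key = j * n + h if j < h else h * n + j
            d += r ** st.in2.get(key, 0)
    return d


@njit(cache=True)
def _chg_add(st, mdl, i, j, out):
    n = st.n
    for a in range(len(mdl.codes)):
        c = mdl.codes[a]
        lam = mdl.lambdas[a]
        d = 0.0
        if c == ARC:
            d = 1.0
        elif c == RECIP:
            d = 1.0 if j * n + i in st.arc_set else 0.0
        elif c == AINS:
            r = 1.0 - 1.0 / lam
            d = lam * (1.0 - r ** len(st.in_adj[j]))
        elif c == AOUTS:
            r = 1.0 - 1.0 / lam
            d = lam * (1.0 - r ** len(st.out_adj[i]))
        elif c == ATT:
            r = 1.0 - 1.0 / lam
            d = lam * (1.0 - r ** st.mix2.get(i * n + j, 0))
            for h in st.out_adj[j]:
                if h != i and i * n + h in st.arc_set:
                    d += r ** st.mix2.get(i * n + h, 0)
            for h in st.in_adj[i]:
                if h != j and h * n + j in st.arc_set:
                    d += r ** st.mix2.get(h * n + j, 0)
        elif c == ATC:
            r = 1.0 - 1.0 / lam
            d = lam * (1.0 - r ** st.mix2.get(j * n + i, 0))
            for h in st.out_adj[j]:
                if h != i and h * n + i in st.arc_set:
                    d += r ** st.mix2.get(i * n + h, 0)
            for h in st.in_adj[i]:
                if h != j and j * n + h in st.arc_set:
                    d += r ** st.mix2.get(h * n + j, 0)
        elif c == AKTD:
            r = 1.0 - 1.0 / lam
            key = i * n + j if i < j else j * n + i
            d = lam * (1.0 - r ** st.in2.get(key, 0))
            for h in st.out_adj[i]:
                if h != j:
                    w = 0
                    if j * n + h in st.arc_set:
                        w += 1
                    if h * n + j in st.arc_set:
                        w += 1
                    if w > 0:
                        k2 = j * n + h if j < h else h * n + j
                        d += w * r ** st.in2.get(k2, 0)
        elif c == AKTU:
            r = 1.0 - 1.0 / lam
            key = i * n + j if i < j else j * n + i
            d = lam * (1.0 - r ** st.out2.get(key, 0))
            for h in st.in_adj[j]:
                if h != i:
                    w = 0
                    if i * n + h in st.arc_set:
                        w += 1
                    if h * n + i in st.arc_set:
                        w += 1
                    if w > 0:
                        k2 = i * n + h if i < h else h * n + i
                        d += w * r ** st.out2.get(k2, 0)
        elif c == A2PT:
            d = _d_a2pt(st, lam, i, j)
        elif c == A2PD:
            d = _d_a2pd(st, lam, i, j)
        elif c == A2PTD:
            d = _d_a2pt(st, lam, i, j) + 0.5 * _d_a2pd(st, lam, i, j)
        elif c == A2PU:
            r = 1.0 - 1.0 / lam
            for h in st.in_adj[j]:
                if h != i:
                    key = i * n + h if i < h else h * n + i
                    d += r ** st.out2.get(key, 0)
        elif c == ISOL:
            if len(st.in_adj[i]) + len(st.out_adj[i]) == 0:
                d -= 1.0
            if len(st.in_adj[j]) + len(st.out_adj[j]) == 0:
                d -= 1.0
        elif c == SENDER or c == CSENDER:
            arr = mdl.battrs if c == SENDER else mdl.uattrs
            v = arr[mdl.attr_idx[a], i]
            d = 0.0 if np.isnan(v) else v
        elif c == RECEIVER or c == CRECEIVER:
            arr = mdl.battrs if c == RECEIVER else mdl.uattrs
            v = arr[mdl.attr_idx[a], j]
            d = 0.0 if np.isnan(v) else v
        elif c == INTER:
            vi = mdl.battrs[mdl.attr_idx[a], i]
            vj = mdl.battrs[mdl.attr_idx[a], j]
            d = 0.0 if (np.isnan(vi) or np.isnan(vj)) else vi * vj
        elif c == CDIFF:
            vi = mdl.uattrs[mdl.attr_idx[a], i]
            vj = mdl.uattrs[mdl.attr_idx[a], j]
            d = 0.0 if (np.isnan(vi) or np.isnan(vj)) else abs(vi - vj)
        else:  # categorical
            ci = mdl.cattrs[mdl.attr_idx[a], i]
            cj = mdl.cattrs[mdl.attr_idx[a], j]
            if ci >= 0 and cj >= 0:
                same = ci == cj
                if c == MATCH:
                    d = 1.0 if same else 0.0
                elif c == MISMATCH:
                    d = 0.0 if same else 1.0
                elif c == MATCHR:
                    d = 1.0 if (same and j * n + i in st.arc_set) else 0.0
                elif c == MISMATCHR:
                    d = 1.0 if ((not same) and j * n + i in st.arc_set) else 0.0
        out[a] = d


@njit(cache=True)
def _chg_del(st, mdl, i, j, out):
    """Deletion change statistics z(x - arc) - z(x), computed with the arc
    (i, j) still present.

    Mirrors :func:`_chg_add` evaluated on the post-deletion graph: two-path
    counts that include a path through the arc itself are corrected by -1
    (mix2(i,h) for h in out(j), mix2(h,j) for h in in(i), in2{j,h} for h in
    out(i), out2{i,h} for h in in(j)), degrees lose the arc's contribution,
    and the result is negated.  Avoids the delete/re-add round trip on
    rejected deletion proposals.
    """
    n = st.n
    for a in range(len(mdl.codes)):
        c = mdl.codes[a]
        lam = mdl.lambdas[a]
        d = 0.0
        if c == ARC:
            d = 1.0
        elif c == RECIP:
            d = 1.0 if j * n + i in st.arc_set else 0.0
        elif c == AINS:
            r = 1.0 - 1.0 / lam
            d = lam * (1.0 - r ** (len(st.in_adj[j]) - 1))
        elif c == AOUTS:
            r = 1.0 - 1.0 / lam
            d = lam * (1.0 - r ** (len(st.out_adj[i]) - 1))
        elif c == ATT:
            r = 1.0 - 1.0 / lam
            d = lam * (1.0 - r ** st.mix2.get(i * n + j, 0))
            for h in st.out_adj[j]:
                if h != i and i * n + h in st.arc_set:
                    d += r ** (st.mix2.get(i * n + h, 0) - 1)
            for h in st.in_adj[i]:
                if h != j and h * n + j in st.arc_set:
                    d += r ** (st.mix2.get(h * n + j, 0) - 1)
        elif c == ATC:
            r = 1.0 - 1.0 / lam
            d = lam * (1.0 - r ** st.mix2.get(j * n + i, 0))
            for h in st.out_adj[j]:
                if h != i and h * n + i in st.arc_set:
                    d += r ** (st.mix2.get(i * n + h, 0) - 1)
            for h in st.in_adj[i]:
                if h != j and j * n + h in st.arc_set:
                    d += r ** (st.mix2.get(h * n + j, 0) - 1)
        elif c == AKTD:
            r = 1.0 - 1.0 / lam
            key = i * n + j if i < j else j * n + i
            d = lam * (1.0 - r ** st.in2.get(key, 0))
            for h in st.out_adj[i]:
                if h != j:
                    w = 0
                    if j * n + h in st.arc_set:
                        w += 1
                    if h * n + j in st.arc_set:
                        w += 1
                    if w > 0:
                        k2 = j * n + h if j < h else h * n + j
                        d += w * r ** (st.in2.get(k2, 0) - 1)
        elif c == AKTU:
            r = 1.0 - 1.0 / lam
            key = i * n + j if i < j else j * n + i
            d = lam * (1.0 - r ** st.out2.get(key, 0))
            for h in st.in_adj[j]:
                if h != i:
                    w = 0
                    if i * n + h in st.arc_set:
                        w += 1
                    if h * n + i in st.arc_set:
                        w += 1
                    if w > 0:
                        k2 = i * n + h if i < h else h * n + i
                        d += w * r ** (st.out2.get(k2, 0) - 1)
        elif c == A2PT:
            r = 1.0 - 1.0 / lam
            for h in st.out_adj[j]:
                if h != i and i < h:
                    d += r ** (st.mix2.get(i * n + h, 0) - 1)
            for h in st.in_adj[i]:
                if h != j and h < j:
                    d += r ** (st.mix2.get(h * n + j, 0) - 1)
        elif c == A2PD:
            r = 1.0 - 1.0 / lam
            for h in st.out_adj[i]:
                if h != j:
                    key = j * n + h if j < h else h * n + j
                    d += r ** (st.in2.get(key, 0) - 1)
        elif c == A2PTD:
            r = 1.0 - 1.0 / lam
            for h in st.out_adj[j]:
                if h != i and i < h:
                    d += r ** (st.mix2.get(i * n + h, 0) - 1)
            for h in st.in_adj[i]:
                if h != j and h < j:
                    d += r ** (st.mix2.get(h * n + j, 0) - 1)
            dd = 0.0
            for h in st.out_adj[i]:
                if h != j:
                    key = j * n + h if j < h else h * n + j
                    dd += r ** (st.in2.get(key, 0) - 1)
            d += 0.5 * dd
        elif c == A2PU:
            r = 1.0 - 1.0 / lam
            for h in st.in_adj[j]:
                if h != i:
                    key = i * n + h if i < h else h * n + i
                    d += r ** (st.out2.get(key, 0) - 1)
        elif c == ISOL:
            if len(st.in_adj[i]) + len(st.out_adj[i]) == 1:
                d -= 1.0
            if len(st.in_adj[j]) + len(st.out_adj[j]) == 1:
                d -= 1.0
        elif c == SENDER or c == CSENDER:
            arr = mdl.battrs if c == SENDER else mdl.uattrs
            val = arr[mdl.attr_idx[a], i]
            d = 0.0 if np.isnan(val) else val
        elif c == RECEIVER or c == CRECEIVER:
            arr = mdl.battrs if c == RECEIVER else mdl.uattrs
            val = arr[mdl.attr_idx[a], j]
            d = 0.0 if np.isnan(val) else val
        elif c == INTER:
            vi = mdl.battrs[mdl.attr_idx[a], i]
            vj = mdl.battrs[mdl.attr_idx[a], j]
            d = 0.0 if (np.isnan(vi) or np.isnan(vj)) else vi * vj
        elif c == CDIFF:
            vi = mdl.uattrs[mdl.attr_idx[a], i]
            vj = mdl.uattrs[mdl.attr_idx[a], j]
            d = 0.0 if (np.isnan(vi) or np.isnan(vj)) else abs(vi - vj)
        else:
            ci = mdl.cattrs[mdl.attr_idx[a], i]
            cj = mdl.cattrs[mdl.attr_idx[a], j]
            if ci >= 0 and cj >= 0:
                same = ci == cj
                if c == MATCH:
                    d = 1.0 if same else 0.0
                elif c == MISMATCH:
                    d = 0.0 if same else 1.0
                elif c == MATCHR:
                    d = 1.0 if (same and j * n + i in st.arc_set) else 0.0
                elif c == MISMATCHR:
                    d = 1.0 if ((not same) and j * n + i in st.arc_set) else 0.0
        out[a] = -d


# ---------------------------------------------------------------------------
# Metropolis-Hastings proposals
# ---------------------------------------------------------------------------

@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def _propose_basic(st, mdl, theta, dz, buf):
    """One basic-sampler proposal (uniform dyad toggle).

    Returns (accepted, was_add, i, j)."""
    n = st.n
    i = np.random.randint(n)
    j = np.random.randint(n - 1)
    if j >= i:
        j += 1
    p = len(theta)
    if i * n + j in st.arc_set:
        _chg_del(st, mdl, i, j, buf)
        lp = 0.0
        for a in range(p):
            lp += theta[a] * buf[a]
        if lp >= 0.0 or np.random.random() < np.exp(lp):
            _del_arc(st, i, j)
            for a in range(p):
                dz[a] += buf[a]
            return 1, 0, i, j
        return 0, 0, i, j
    _chg_add(st, mdl, i, j, buf)
    lp = 0.0
    for a in range(p):
        lp += theta[a] * buf[a]
    if lp >= 0.0 or np.random.random() < np.exp(lp):
        _add_arc(st, i, j)
        for a in range(p):
            dz[a] += buf[a]
        return 1, 1, i, j
    return 0, 1, i, j


@njit(cache=True)
def _run_basic(st, mdl, theta, dz, nsteps):
    buf = np.empty(len(theta))
    acc = 0
    for _ in range(nsteps):
        a, _, _, _ = _propose_basic(st, mdl, theta, dz, buf)
        acc += a
    return acc


@njit(cache=True)
def _propose_ifd(st, mdl, theta, dz, buf, L0, v):
    """One improved-fixed-density proposal.

    The proposal type is state-driven: at the observed arc count L0 an
    insertion of a uniform absent dyad is proposed, at L0+1 a deletion of
    a uniform arc, so the count never leaves {L0, L0+1}.  The auxiliary
    parameter v enters the acceptance log-probability with + for adds and
    - for deletes.  Returns (accepted, was_add, i, j).
    """
    n = st.n
    p = len(theta)
    m = st.meta[0]
    if m <= L0:
        # uniform absent dyad by rejection
        while True:
            i = np.random.randint(n)
            j = np.random.randint(n - 1)
            if j >= i:
                j += 1
            if i * n + j not in st.arc_set:
                break
        _chg_add(st, mdl, i, j, buf)
        lp = v
        for a in range(p):
            lp += theta[a] * buf[a]
        if lp >= 0.0 or np.random.random() < np.exp(lp):
            _add_arc(st, i, j)
            for a in range(p):
                dz[a] += buf[a]
            return 1, 1, i, j
        return 0, 1, i, j
    k = np.random.randint(m)
    i = st.tails[k]
    j = st.heads[k]
    _chg_del(st, mdl, i, j, buf)
    lp = -v
    for a in range(p):
        lp += theta[a] * buf[a]
    if lp >= 0.0 or np.random.random() < np.exp(lp):
        _del_arc(st, i, j)
        for a in range(p):
            dz[a] += buf[a]
        return 1, 0, i, j
    return 0, 0, i, j


@njit(cache=True)
def _run_ifd(st, mdl, theta, dz, nsteps, L0, v, adapt_rate, adapting):
    """Run nsteps IFD proposals; returns (accept count, updated v).

    During adaptation v is nudged so that insertion and deletion
    acceptance rates balance: an accepted add lowers v, a rejected add
    raises it, and symmetrically for deletes.
    """
    buf = np.empty(len(theta))
    acc = 0
    for _ in range(nsteps):
        accepted, was_add, _, _ = _propose_ifd(st, mdl, theta, dz, buf, L0, v)
        acc += accepted
        if adapting:
            if was_add == 1:
                v += -adapt_rate if accepted == 1 else adapt_rate
            else:
                v += adapt_rate if accepted == 1 else -adapt_rate
    return acc, v


@njit(cache=True)
def _ifd_restore(st, mdl, theta, dz, L0, v):
    """Continue delete proposals until the arc count is back at L0."""
    buf = np.empty(len(theta))
    tries = 0
    while st.meta[0] > L0:
        _propose_ifd(st, mdl, theta, dz, buf, L0, v)
        tries += 1
        if tries > 10_000_000:
            raise RuntimeError("IFD density restoration did not terminate")
    return tries


@njit(cache=True)
def _cd_chain(st, mdl, theta, dz, nsteps, mode, L0, v, adapt_rate):
    """One contrastive-divergence burst that reverts its own toggles.

    Runs ``nsteps`` proposals (mode 0: basic, 1: IFD with adaptation of
    v), in IFD mode restores the arc count to L0, then undoes every
    accepted toggle in reverse order so the state is back at the start
    without rebuilding the graph.  dz keeps the burst's final divergence;
    the caller zeroes it before the next burst.  Returns updated v.
    """
    cap = 2 * nsteps + 1024
    li = np.empty(cap, np.int64)
    lj = np.empty(cap, np.int64)
    la = np.empty(cap, np.int64)
    nl = 0
    buf = np.empty(len(theta))
    for _ in range(nsteps):
        if mode == 0:
            acc, wa, i, j = _propose_basic(st, mdl, theta, dz, buf)
        else:
            acc, wa, i, j = _propose_ifd(st, mdl, theta, dz, buf, L0, v)
            if wa == 1:
                v += -adapt_rate if acc == 1 else adapt_rate
            else:
                v += adapt_rate if acc == 1 else -adapt_rate
        if acc == 1:
            li[nl] = i
            lj[nl] = j
            la[nl] = wa
            nl += 1
    if mode == 1:
        while st.meta[0] > L0 and nl < cap:
            acc, wa, i, j = _propose_ifd(st, mdl, theta, dz, buf, L0, v)
            if acc == 1:
                li[nl] = i
                lj[nl] = j
                la[nl] = wa
                nl += 1
    for k in range(nl - 1, -1, -1):
        if la[k] == 1:
            _del_arc(st, li[k], lj[k])
        else:
            _add_arc(st, li[k], lj[k])
    return v


@njit(cache=True)
def _run_basic_census(st, mdl, theta, dz, nsteps):
    """Basic sampler on n<=3 recording the visited 6-bit digraph codes."""
    n = st.n
    counts = np.zeros(64, np.int64)
    buf = np.empty(len(theta))
    for _ in range(nsteps):
        _propose_basic(st, mdl, theta, dz, buf)
        code = 0
        b = 0
        for i in range(n):
            for j in range(n):
                if i != j:
                    if i * n + j in st.arc_set:
                        code |= 1 << b
                    b += 1
        counts[code] += 1
    return counts


@njit(cache=True)
def _run_ifd_census(st, mdl, theta, dz, nsteps, L0, v):
    """IFD sampler on n<=3 recording codes of states at the observed count."""
    n = st.n
    counts = np.zeros(64, np.int64)
    buf = np.empty(len(theta))
    for _ in range(nsteps):
        _propose_ifd(st, mdl, theta, dz, buf, L0, v)
        if st.meta[0] == L0:
            code = 0
            b = 0
            for i in range(n):
                for j in range(n):
                    if i != j:
                        if i * n + j in st.arc_set:
                            code |= 1 << b
                        b += 1
            counts[code] += 1
    return counts


# ---------------------------------------------------------------------------
# Python-side wrappers
# ---------------------------------------------------------------------------

def seed_rng(seed: int) -> None:
    """Seed the kernels' RNG stream (shared across subsequent kernel calls)."""
    _seed(int(seed) % 2 ** 32)


def default_capacity(n_nodes: int, n_arcs: int) -> int:
    """Preallocated arc capacity: everything for small graphs, a generous
    sparse headroom for large ones."""
    full = n_nodes * (n_nodes - 1)
    if n_nodes <= 300:
        return full
    return min(full, max(4 * n_arcs + 1000, 60 * n_nodes))


def build_state(n_nodes: int, arcs: np.ndarray | None = None,
                capacity: int | None = None) -> GState:
    """Create a compiled-sampler state, optionally filled with arcs."""
    if arcs is None:
        arcs = np.empty((0, 2), dtype=np.int64)
    arcs = np.asarray(arcs, dtype=np.int64).reshape(-1, 2)
    if capacity is None:
        capacity = default_capacity(n_nodes, len(arcs))
    st = _empty_state(n_nodes, capacity)
    if len(arcs):
        _fill_state(st, np.ascontiguousarray(arcs[:, 0]),
                    np.ascontiguousarray(arcs[:, 1]))
    return st


def state_from_graph(g: DirectedGraph, capacity: int | None = None) -> GState:
    return build_state(g.n_nodes, g.arcs_array(), capacity)


def state_arcs(st: GState) -> np.ndarray:
    m = int(st.meta[0])
    out = np.empty((m, 2), dtype=np.int64)
    out[:, 0] = st.tails[:m]
    out[:, 1] = st.heads[:m]
    return out


def state_to_graph(st: GState) -> DirectedGraph:
    return DirectedGraph.from_arcs(int(st.n), state_arcs(st))


def encode_model(model: ModelSpec, attrs: AttributeSet | None,
                 n_nodes: int) -> CModel:
    """Flatten a ModelSpec (and the attribute columns it references) into
    the array form the kernels consume."""
    p = len(model)
    codes = np.empty(p, dtype=np.int64)
    lambdas = np.ones(p, dtype=np.float64)
    attr_idx = np.zeros(p, dtype=np.int64)
    brows: list[np.ndarray] = []
    crows: list[np.ndarray] = []
    urows: list[np.ndarray] = []
    seen: dict[tuple[str, str], int] = {}
    for a, eff in enumerate(model):
        codes[a] = eff.code
        if eff.lam is not None:
            lambdas[a] = eff.lam
        if eff.attr is not None:
            kind = ATTR_KIND[eff.name]
            if attrs is None:
                raise ValueError(f"{eff.label} requires node attributes")
            table = getattr(attrs, kind)
            if eff.attr not in table:
                raise KeyError(
                    f"{eff.name} needs {kind} attribute {eff.attr!r}")
            key = (kind, eff.attr)
            if key not in seen:
                rows = {"binary": brows, "categorical": crows,
                        "continuous": urows}[kind]
                seen[key] = len(rows)
                rows.append(np.asarray(table[eff.attr]))
            attr_idx[a] = seen[key]

    def stack(rows, dtype, fill):
        if not rows:
            return np.full((1, n_nodes), fill, dtype=dtype)
        return np.ascontiguousarray(np.stack(rows).astype(dtype))

    return CModel(codes, lambdas, attr_idx,
                  stack(brows, np.float64, np.nan),
                  stack(crows, np.int64, -1),
                  stack(urows, np.float64, np.nan))


def change_stats(g: DirectedGraph, model: ModelSpec,
                 attrs: AttributeSet | None, i: int, j: int,
                 is_add: bool = True) -> np.ndarray:
    """Compiled signed change-statistic vector for toggling arc (i, j);
    test hook (the sampler kernels call _chg_add/_chg_del directly)."""
    st = state_from_graph(g)
    mdl = encode_model(model, attrs, g.n_nodes)
    out = np.empty(len(model))
    if is_add:
        _chg_add(st, mdl, int(i), int(j), out)
    else:
        _chg_del(st, mdl, int(i), int(j), out)
    return out
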