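"""Array/compiled representation of a mass-action network.

Generic numba kernels operate on flat arrays so they compile once per process
and serve every network.  Reactions are restricted to order <= 2 (plus
zero-order source reactions, used by toy birth processes); homodimerizations
use the n(n-1)/2 propensity stochastically and n^2/2 deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .network import ReactionNetwork


@dataclass
class CompiledNetwork:
    """Flat-array view of a :class:`ReactionNetwork` for the kernels."""

    k: np.ndarray        # rate constants, float64[nr]
    re1: np.ndarray      # first reactant species index or -1, int64[nr]
    re2: np.ndarray      # second reactant species index or -1, int64[nr]
    homod: np.ndarray    # A+A reaction flag, bool[nr]
    S: np.ndarray        # stoichiometric matrix (clamped rows zeroed), int64[ns, nr]
    dep_ptr: np.ndarray  # CSR pointers into dep_idx: reactions to refresh after j fires
    dep_idx: np.ndarray
    col_ptr: np.ndarray  # CSC pointers: nonzero stoichiometry entries per reaction
    col_idx: np.ndarray  # species index of each nonzero entry
    col_val: np.ndarray  # integer stoichiometric change of each nonzero entry

    @property
    def n_species(self) -> int:
        return self.S.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]


def compile_network(network: ReactionNetwork) -> CompiledNetwork:
    ns, nr = network.n_species, network.n_reactions
    pos = {s.id: i for i, s in enumerate(network.species)}
    k = np.empty(nr)
    re1 = np.full(nr, -1, dtype=np.int64)
    re2 = np.full(nr, -1, dtype=np.int64)
    homod = np.zeros(nr, dtype=np.bool_)
    for j, r in enumerate(network.reactions):
        k[j] = r.rate_constant
        flat = []
        for sid, c in r.reactants:
            flat.extend([pos[sid]] * c)
        if len(flat) >= 1:
            re1[j] = flat[0]
        if len(flat) == 2:
            re2[j] = flat[1]
            homod[j] = flat[0] == flat[1]
    S = network.stoichiometric_matrix().astype(np.int64)

    # reaction dependency graph: firing j changes species with S[:, j] != 0;
    # refresh propensities of reactions consuming those species (and j itself)
    consumers: list[set[int]] = [set() for _ in range(ns)]
    for j in range(nr):
        for i in (re1[j], re2[j]):
            if i >= 0:
                consumers[i].add(j)
    dep: list[np.ndarray] = []
    for j in range(nr):
        touched: set[int] = {j}
        for i in np.nonzero(S[:, j])[0]:
            touched |= consumers[i]
        dep.append(np.array(sorted(touched), dtype=np.int64))
    dep_ptr = np.zeros(nr + 1, dtype=np.int64)
    for j in range(nr):
        dep_ptr[j + 1] = dep_ptr[j] + len(dep[j])
    dep_idx = np.concatenate(dep) if nr else np.zeros(0, dtype=np.int64)
    col_ptr = np.zeros(nr + 1, dtype=np.int64)
    col_idx_list, col_val_list = [], []
    for j in range(nr):
        nz = np.nonzero(S[:, j])[0]
        col_ptr[j + 1] = col_ptr[j] + nz.size
        col_idx_list.append(nz.astype(np.int64))
        col_val_list.append(S[nz, j].astype(np.int64))
    col_idx = (
        np.concatenate(col_idx_list) if nr else np.zeros(0, dtype=np.int64)
    )
    col_val = (
        np.concatenate(col_val_list) if nr else np.zeros(0, dtype=np.int64)
    )
    return CompiledNetwork(
        k, re1, re2, homod, S, dep_ptr, dep_idx, col_ptr, col_idx, col_val
    )


@njit(cache=True, fastmath=True, inline="always")
def _propensity(j, x, k, re1, re2, homod, stochastic):
    a = k[j]
    i1 = re1[j]
    if i1 >= 0:
        n1 = x[i1]
        if n1 < 0.0:
            n1 = 0.0
        i2 = re2[j]
        if i2 < 0:
            a *= n1
        elif homod[j]:
            if stochastic:
                a *= n1 * (n1 - 1.0) * 0.5
            else:
                a *= n1 * n1 * 0.5
        else:
            n2 = x[i2]
            if n2 < 0.0:
                n2 = 0.0
            a *= n1 * n2
    return a if a > 0.0 else 0.0


@njit(cache=True)
def mass_action_rates(x, k, re1, re2, homod, stochastic):
    nr = k.shape[0]
    a = np.empty(nr)
    for j in range(nr):
        a[j] = _propensity(j, x, k, re1, re2, homod, stochastic)
    return a


@njit(cache=True)
def ode_rhs(x, k, re1, re2, homod, S):
    ns, nr = S.shape
    dx = np.zeros(ns)
    for j in range(nr):
        a = _propensity(j, x, k, re1, re2, homod, False)
        if a != 0.0:
            for i in range(ns):
                s = S[i, j]
                if s != 0:
                    dx[i] += s * a
    return dx


@njit(cache=True)
def ode_jac(x, k, re1, re2, homod, S):
    ns, nr = S.shape
    J = np.zeros((ns, ns))
    for j in range(nr):
        i1 = re1[j]
        if i1 < 0:
            continue
        i2 = re2[j]
        n1 = x[i1] if x[i1] > 0.0 else 0.0
        if i2 < 0:
            d1 = k[j]
            for i in range(ns):
                if S[i, j] != 0:
                    J[i, i1] += S[i, j] * d1
        elif homod[j]:
            d1 = k[j] * n1
            for i in range(ns):
                if S[i, j] != 0:
                    J[i, i1] += S[i, j] * d1
        else:
            n2 = x[i2] if x[i2] > 0.0 else 0.0
            d1 = k[j] * n2
            d2 = k[j] * n1
            for i in range(ns):
                if S[i, j] != 0:
                    J[i, i1] += S[i, j] * d1
                    J[i, i2] += S[i, j] * d2
    return J


@njit(cache=True, fastmath=True)
def ssa_direct(x0, k, re1, re2, homod, col_ptr, col_idx, col_val,
               dep_ptr, dep_idx, t_grid, seed):
    """Exact direct-method Gillespie path sampled onto t_grid (last-event hold)."""
    np.random.seed(seed)
    ns = x0.shape[0]
    nr = k.shape[0]
    ng = t_grid.shape[0]
    x = x0.astype(np.float64)
    out = np.empty((ng, ns), dtype=np.int64)
    a = mass_action_rates(x, k, re1, re2, homod, True)
    asum = a.sum()
    t = t_grid[0]
    gi = 0
    for i in range(ns):
        out[gi, i] = np.int64(x[i])
    gi += 1
    steps_since_refresh = 0
    while gi < ng:
        if asum <= 1e-300:
            for g in range(gi, ng):
                for i in range(ns):
                    out[g, i] = np.int64(x[i])
            gi = ng
            break
        tau = -np.log(np.random.random()) / asum
        t_next = t + tau
        while gi < ng and t_grid[gi] <= t_next:
            for i in range(ns):
                out[gi, i] = np.int64(x[i])
            gi += 1
        if gi >= ng:
            break
        t = t_next
        # select reaction
        r = np.random.random() * asum
        c = 0.0
        j = nr - 1
        for jj in range(nr):
            c += a[jj]
            if r <= c:
                j = jj
                break
        for p in range(col_ptr[j], col_ptr[j + 1]):
            x[col_idx[p]] += col_val[p]
        for p in range(dep_ptr[j], dep_ptr[j + 1]):
            jj = dep_idx[p]
            anew = _propensity(jj, x, k, re1, re2, homod, True)
            asum += anew - a[jj]
            a[jj] = anew
        steps_since_refresh += 1
        if steps_since_refresh >= 50000:
            a = mass_action_rates(x, k, re1, re2, homod, True)
            asum = a.sum()
            steps_since_refresh = 0
    return out


@njit(cache=True, fastmath=True)
def ssa_tau_leap(x0, k, re1, re2, homod, col_ptr, col_idx, col_val,
                 dep_ptr, dep_idx, t_grid, seed, eps, exact_threshold):
    """Adaptive tau-leaping (bounded relative propensity change), with exact
    SSA stepping whenever the selected leap would be smaller than
    ``exact_threshold`` expected events.

    Species participating only in fast near-equilibrium cycles are protected
    by the Cao-Gillespie bound; the leap is rejected and halved on any
    negative excursion.
    """
    np.random.seed(seed)
    ns = x0.shape[0]
    nr = k.shape[0]
    ng = t_grid.shape[0]
    x = x0.astype(np.float64)
    out = np.empty((ng, ns), dtype=np.int64)
    t = t_grid[0]
    gi = 0
    for i in range(ns):
        out[gi, i] = np.int64(x[i])
    gi += 1
    # highest reaction order in which each species appears as a reactant
    g = np.ones(ns)
    for j in range(nr):
        if re2[j] >= 0:
            i1 = re1[j]
            i2 = re2[j]
            hv = 3.0 if homod[j] else 2.0
            if g[i1] < hv:
                g[i1] = hv
            if i2 >= 0 and g[i2] < 2.0:
                g[i2] = 2.0
    mu = np.zeros(ns)
    s2 = np.zeros(ns)
    while gi < ng:
        a = mass_action_rates(x, k, re1, re2, homod, True)
        asum = a.sum()
        if asum <= 1e-300:
            for gg in range(gi, ng):
                for i in range(ns):
                    out[gg, i] = np.int64(x[i])
            gi = ng
            break
        # candidate tau from the Cao-Gillespie species bound (sparse)
        for i in range(ns):
            mu[i] = 0.0
            s2[i] = 0.0
        for j in range(nr):
            aj = a[j]
            if aj > 0.0:
                for p in range(col_ptr[j], col_ptr[j + 1]):
                    i = col_idx[p]
                    s = col_val[p]
                    mu[i] += s * aj
                    s2[i] += s * s * aj
        tau = t_grid[ng - 1] - t
        for i in range(ns):
            if mu[i] == 0.0 and s2[i] == 0.0:
                continue
            bound = eps * x[i] / g[i]
            if bound < 1.0:
                bound = 1.0
            if mu[i] != 0.0:
                c1 = bound / abs(mu[i])
                if c1 < tau:
                    tau = c1
            if s2[i] > 0.0:
                c2 = bound * bound / s2[i]
                if c2 < tau:
                    tau = c2
        if tau * asum < exact_threshold:
            # exact stepping for a burst of events
            for _ in range(100):
                if asum <= 1e-300:
                    break
                dt = -np.log(np.random.random()) / asum
                t_next = t + dt
                while gi < ng and t_grid[gi] <= t_next:
                    for i in range(ns):
                        out[gi, i] = np.int64(x[i])
                    gi += 1
                if gi >= ng:
                    break
                t = t_next
                r = np.random.random() * asum
                c = 0.0
                j = nr - 1
                for jj in range(nr):
                    c += a[jj]
                    if r <= c:
                        j = jj
                        break
                for p in range(col_ptr[j], col_ptr[j + 1]):
                    x[col_idx[p]] += col_val[p]
                for p in range(dep_ptr[j], dep_ptr[j + 1]):
                    jj = dep_idx[p]
                    anew = _propensity(jj, x, k, re1, re2, homod, True)
                    asum += anew - a[jj]
                    a[jj] = anew
            continue
        # Poisson leap; halve tau until no species goes negative
        accepted = False
        while not accepted:
            xn = x.copy()
            for j in range(nr):
                if a[j] > 0.0:
                    nj = np.random.poisson(a[j] * tau)
                    if nj > 0:
                        for p in range(col_ptr[j], col_ptr[j + 1]):
                            xn[col_idx[p]] += col_val[p] * nj
            ok = True
            for i in range(ns):
                if xn[i] < 0.0:
                    ok = False
                    break
            if ok:
                accepted = True
                t_next = t + tau
                while gi < ng and t_grid[gi] <= t_next:
                    for i in range(ns):
                        out[gi, i] = np.int64(x[i])
                    gi += 1
                t = t_next
                x = xn
            else:
                tau *= 0.5
                if tau * asum < 1.0:
                    # fall back: single exact event
                    dt = -np.log(np.random.random()) / asum
                    t_next = t + dt
                    while gi < ng and t_grid[gi] <= t_next:
                        for i in range(ns):
                            out[gi, i] = np.int64(x[i])
                        gi += 1
                    if gi >= ng:
                        accepted = True
                        break
                    t = t_next
                    r = np.random.random() * asum
                    c = 0.0
                    j = nr - 1
                    for jj in range(nr):
                        c += a[jj]
                        if r <= c:
                            j = jj
                            break
                    for p in range(col_ptr[j], col_ptr[j + 1]):
                        x[col_idx[p]] += col_val[p]
                    accepted = True
    return out
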