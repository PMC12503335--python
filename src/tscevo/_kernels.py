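"""Numba-compiled numerical cores of the interaction model.

These kernels are the hot path of the evolutionary loop (they are executed
hundreds of times per generation); their semantics are mirrored by plain
Python/numpy code in the test suite's oracles.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def interaction_matrix_kernel(promoters, mids, orients, L, c, d_max):
    """Pairwise supercoiling-coupling coefficients d(sigma_i)/d(e_j).

    Entry (i, j) = eta * c * max(1 - d(i, j) / d_max, 0), where d(i, j) is
    the shortest circular distance from gene i's promoter to gene j's middle
    and eta follows the twin-domain sign rules (upstream co-oriented gene:
    +1; upstream contra-oriented: -1; signs reversed downstream). Diagonal
    and exact antipodal ties are 0.
    """
    n = promoters.shape[0]
    M = np.zeros((n, n))
    for i in range(n):
        p = promoters[i]
        fwd_i = orients[i] > 0
        for j in range(n):
            if i == j:
                continue
            delta = (mids[j] - p) % L
            if 2.0 * delta == L:
                continue
            if 2.0 * delta < L:
                dist = delta
                clockwise = True
            else:
                dist = L - delta
                clockwise = False
            if dist >= d_max:
                continue
            downstream = clockwise == fwd_i
            same_strand = (orients[i] > 0) == (orients[j] > 0)
            # upstream & same -> +1 ; upstream & opposite -> -1 ; reversed downstream
            if (not downstream) == same_strand:
                eta = 1.0
            else:
                eta = -1.0
            M[i, j] = eta * c * (1.0 - dist / d_max)
    return M


@njit(cache=False)
def matrix_batch_kernel(promoters, mids, orients, L, c, d_max):
    """Interaction matrices for a batch of genomes (stacked leading axis)."""
    u, n = promoters.shape
    out = np.empty((u, n, n))
    for g in range(u):
        out[g] = interaction_matrix_kernel(promoters[g], mids[g], orients[g], L, c, d_max)
    return out


@njit(cache=False)
def mutate_arrays_kernel(begins0, lengths0, orients0, L, draws):
    """Apply a sequence of genomic inversions to begin-sorted gene arrays.

    ``draws`` holds, per inversion, two uniform integers in [0, T) where T is
    the (invariant) total intergenic length; each is mapped onto the current
    intergenic layout to give a breakpoint, and the non-wrapping arc between
    the two breakpoints is inverted in place. Returns the new (begins,
    lengths, orients) arrays plus the permutation of the original gene
    records (mirroring a run of genes reverses their order, so the arrays
    stay begin-sorted throughout).
    """
    n = begins0.shape[0]
    begins = begins0.copy()
    lengths = lengths0.copy()
    orients = orients0.copy()
    perm = np.arange(n)
    seg_start = np.empty(n, np.int64)
    cum = np.empty(n, np.int64)
    pos = np.empty(2, np.int64)
    tmpb = np.empty(n, np.int64)
    tmpl = np.empty(n, np.int64)
    tmpo = np.empty(n, np.int64)
    tmpp = np.empty(n, np.int64)
    for kk in range(draws.shape[0]):
        # intergenic segment table of the current layout (zero lengths kept;
        # they can never receive a draw)
        total = 0
        for k in range(n):
            s = (begins[k] + lengths[k]) % L
            seg_start[k] = s
            total += (begins[(k + 1) % n] - s) % L if n > 1 else L - lengths[0]
            cum[k] = total
        for j in range(2):
            u = draws[kk, j]
            lo = 0
            hi = n
            while lo < hi:  # bisect_right(cum, u)
                mid = (lo + hi) // 2
                if cum[mid] <= u:
                    lo = mid + 1
                else:
                    hi = mid
            prev = cum[lo - 1] if lo > 0 else 0
            pos[j] = (seg_start[lo] + (u - prev)) % L
        a = min(pos[0], pos[1])
        b = max(pos[0], pos[1])
        i0 = -1
        i1 = -1
        for k in range(n):
            if begins[k] >= a and begins[k] + lengths[k] <= b:
                if i0 < 0:
                    i0 = k
                i1 = k + 1
        if i0 < 0:
            continue  # no gene inside: phenotypically neutral inversion
        width = i1 - i0
        for t in range(width):
            src = i1 - 1 - t
            tmpb[t] = a + b - (begins[src] + lengths[src])
            tmpl[t] = lengths[src]
            tmpo[t] = -orients[src]
            tmpp[t] = perm[src]
        for t in range(width):
            begins[i0 + t] = tmpb[t]
            lengths[i0 + t] = tmpl[t]
            orients[i0 + t] = tmpo[t]
            perm[i0 + t] = tmpp[t]
    return begins, lengths, orients, perm


@njit(cache=False)
def _apply_map(M, sigma_background, sigma_half, epsilon, m, e, ko_mask, sigma, U, raw):
    """One synchronous application of the expression map; fills sigma, U, raw
    in place and returns the max-norm residual |F(e) - e|."""
    n = M.shape[0]
    residual = 0.0
    coupling = np.dot(M, e)  # BLAS gemv
    for i in range(n):
        s = sigma_background + coupling[i]
        sigma[i] = s
        x = (s - sigma_half) / epsilon
        if x > 700.0:
            u = 0.0
        elif x < -700.0:
            u = 1.0
        else:
            u = 1.0 / (1.0 + np.exp(x))
        U[i] = u
        if ko_mask[i]:
            raw[i] = 0.0
        else:
            raw[i] = np.exp(m * (u - 1.0))
        d = abs(raw[i] - e[i])
        if d > residual:
            residual = d
    return residual


@njit(cache=False)
def _newton_polish(M, sigma_background, sigma_half, epsilon, m, e0, ko_mask, tol, max_steps):
    """Newton iteration on F(e) - e = 0 from e0; used to collapse the slow
    geometric tail of the damped substitution once it is safely inside the
    basin of a fixed point. Returns (e, success)."""
    n = M.shape[0]
    e = e0.copy()
    sigma = np.empty(n)
    U = np.empty(n)
    raw = np.empty(n)
    for _ in range(max_steps):
        residual = _apply_map(M, sigma_background, sigma_half, epsilon, m, e, ko_mask, sigma, U, raw)
        if residual < tol:
            return e, True
        # Jacobian of F: diag(m * e_i * dU/dsigma) @ M, with dU/dsigma = -U(1-U)/eps
        A = np.empty((n, n))
        rhs = np.empty(n)
        for i in range(n):
            if ko_mask[i]:
                for j in range(n):
                    A[i, j] = 1.0 if i == j else 0.0
                rhs[i] = 0.0
                continue
            di = raw[i] * m * (-U[i] * (1.0 - U[i]) / epsilon)
            for j in range(n):
                A[i, j] = (1.0 if i == j else 0.0) - di * M[i, j]
            rhs[i] = raw[i] - e[i]
        step = np.linalg.solve(A, rhs)
        bad = False
        for i in range(n):
            if not np.isfinite(step[i]) or abs(step[i]) > 0.5:
                bad = True
                break
        if bad:
            return e, False
        for i in range(n):
            e[i] += step[i]
            if e[i] < -1e-9 or e[i] > 1.0 + 1e-9:
                return e, False
    return e, False


@njit(cache=False)
def _iterate_damped(M, sigma_background, sigma_half, epsilon, m, ko_mask, tol, max_iter,
                    damping, e, sigma, U, raw, e_prev):
    """One damped-substitution attempt from the state already stored in ``e``.

    Convergence means the *undamped* residual |F(e) - e| fell below ``tol``,
    so an accepted point is a genuine fixed point of the original system
    regardless of damping. Three exits keep the attempt cheap: a Newton
    polish collapses the geometric tail once the residual shrinks steadily
    (staying within the basin the iteration already entered); near-repeating
    iterates two steps apart flag a period-2 lock-in; and a residual that
    stops improving flags a longer-period oscillation. The last two abort
    the attempt so the caller can retry with a smaller damping factor.
    """
    n = M.shape[0]
    iterations = 0
    converged = False
    best_residual = 1e300
    prev_residual = 1e300
    monotone = 0
    stale = 0
    newton_failures = 0
    while iterations < max_iter:
        iterations += 1
        residual = _apply_map(M, sigma_background, sigma_half, epsilon, m, e, ko_mask, sigma, U, raw)
        if residual < tol:
            converged = True
            break
        if residual < prev_residual:
            monotone += 1
        else:
            monotone = 0
        prev_residual = residual
        near_root = residual < 1e-3 and iterations % 20 == 0
        steady = monotone >= 20 and iterations % 10 == 0
        if (near_root or steady) and newton_failures < 6:
            cand, ok = _newton_polish(
                M, sigma_background, sigma_half, epsilon, m, e, ko_mask, tol, 12
            )
            far = 0.0
            for i in range(n):
                d = abs(cand[i] - e[i])
                if d > far:
                    far = d
            if ok and far < 0.1:  # same basin: the tail it replaces is small
                for i in range(n):
                    e[i] = cand[i]
                _apply_map(
                    M, sigma_background, sigma_half, epsilon, m, e, ko_mask, sigma, U, raw
                )
                converged = True
                break
            newton_failures += 1
        if residual < 0.99 * best_residual:
            best_residual = residual
            stale = 0
        else:
            stale += 1
            if stale > 100:
                break  # stagnated (longer-period or quasi-periodic oscillation)
        stepdiff = 0.0
        cyclediff = 0.0
        for i in range(n):
            en = raw[i] if damping == 1.0 else e[i] + damping * (raw[i] - e[i])
            d = abs(en - e[i])
            if d > stepdiff:
                stepdiff = d
            if iterations > 1:
                dc = abs(en - e_prev[i])
                if dc > cyclediff:
                    cyclediff = dc
            e_prev[i] = e[i]
            e[i] = en
        # period-2 lock-in: iterates (nearly) repeat two steps apart while
        # still taking large steps (not merely approaching convergence)
        if iterations > 1 and stepdiff > 1000.0 * tol and cyclediff < 1e-3 * stepdiff:
            break
    return iterations, converged


@njit(cache=False)
def solve_ladder_kernel(M, sigma_background, sigma_half, epsilon, m, e_half, ko_mask,
                        tol, base_max_iter, dampings, budget_factor, first_attempt_cap=300):
    """Full fixed-point solve: damping-ladder attempts, each restarted from
    the uniform initial state e_half (knocked-out entries pinned to 0).

    Returns (e, sigma, U, total_iterations, converged, damping_used)."""
    n = M.shape[0]
    e = np.empty(n)
    sigma = np.empty(n)
    U = np.empty(n)
    raw = np.empty(n)
    e_prev = np.empty(n)
    total_iterations = 0
    converged = False
    damping = dampings[0]
    for di in range(dampings.shape[0]):
        damping = dampings[di]
        max_iter = int(budget_factor * base_max_iter / damping)
        if max_iter > 50000:
            max_iter = 50000  # heavier damping converges via the Newton polish
        if di == 0 and dampings.shape[0] > 1 and max_iter > first_attempt_cap:
            # a first undamped attempt that has not converged quickly is very
            # likely oscillating; heavier damping handles it more cheaply
            max_iter = first_attempt_cap
        for i in range(n):
            e[i] = 0.0 if ko_mask[i] else e_half
        iterations, converged = _iterate_damped(
            M, sigma_background, sigma_half, epsilon, m, ko_mask, tol, max_iter,
            damping, e, sigma, U, raw, e_prev,
        )
        total_iterations += iterations
        if converged:
            break
    return e, sigma, U, total_iterations, converged, damping


@njit(cache=False)
def solve_batch_kernel(Ms, backgrounds, sigma_half, epsilon, m, e_half,
                       tol, base_max_iter, dampings, budget_factor):
    """Solve every (genome, environment) system of a population batch.

    ``Ms`` has shape (u, n, n) and ``backgrounds`` (n_env,); returns the
    expression array (u, n_env, n) and a convergence flag array (u, n_env).
    """
    u = Ms.shape[0]
    n = Ms.shape[1]
    n_env = backgrounds.shape[0]
    expressions = np.empty((u, n_env, n))
    ok = np.zeros((u, n_env), np.bool_)
    ko_mask = np.zeros(n, np.bool_)
    for g in range(u):
        for v in range(n_env):
            e, sigma, U, it, conv, damping = solve_ladder_kernel(
                Ms[g], backgrounds[v], sigma_half, epsilon, m, e_half, ko_mask,
                tol, base_max_iter, dampings, budget_factor,
            )
            expressions[g, v, :] = e
            ok[g, v] = conv
    return expressions, ok
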