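"""Compiled inner loop of the simulation engine.

One numba kernel advances the whole action phase of a timestep: agents are
processed strictly sequentially in the supplied random permutation, each
perceiving the grid as left by the agents before it (so foraging
competition through depletion is exact), updating its pending TD
transition, selecting an action epsilon-greedily and executing it.

Perception features are binary, so the kernel stores each agent's pending
perception as the *indices* of its active features (at most 9 of the 18
two-channel features) — Q-value sums and TD weight updates then touch only
those entries, which is arithmetically identical to the dense linear
algebra of :mod:`baldwinsim.learning` but several times cheaper.

All random numbers are pre-drawn outside (one uniform per agent for
exploration, one for the forage roll), so every stream stays on the run's
single numpy Generator.  Exploration reuses its uniform: conditional on
``u < eps`` the rescaled value ``u / eps`` is again uniform and picks the
random action.  Exact Q-value ties resolve to the lowest action index
here; the object-level API (`learning.select_action`) breaks ties
uniformly at random.  Network parameters are float32; per-agent scalars
(energy, skill) stay float64.
"""

from __future__ import annotations

import numba as nb
import numpy as np

__all__ = ["act_phase"]


@nb.njit(cache=True)
def act_phase(
    rtype,  # (m, m) int8 grid resource types, -1 empty
    qty,  # (m, m) int32 grid quantities
    perm,  # (n,) int64 processing order
    row,  # (n,) int64
    col,
    W,  # (n, 5, f) float32 live network weights
    b,  # (n, 5) float32
    skill,  # (n,) float64
    energy,  # (n,) float64
    H,  # (n, 2) int64
    prev_idx,  # (n, 9) int8 active-feature indices of the pending transition
    prev_cnt,  # (n,) int8 number of active features
    prev_a,  # (n,) int8
    prev_r,  # (n,) float32
    has_prev,  # (n,) bool
    u_explore,  # (n,) float64 pre-drawn uniforms
    eat_rolls,  # (n,) float64 pre-drawn uniforms
    learns_actions,  # bool
    learns_skill,  # bool
    type_blind,  # bool
    alpha,  # float64 TD learning rate
    gamma,  # float64 discount
    eps_explore,  # float64
    reward,  # float64 reward magnitude on successful forage
    q,  # float64 skill-success exponent
    eps_energy,  # float64 energy per successful forage
    ds,  # float64 skill increment
    move_cost,  # float64
    whole_cell,  # bool
):
    """Run the action phase for all agents; returns the number of food
    cells emptied (the caller keeps |F| bookkeeping)."""
    m = rtype.shape[0]
    emptied = 0
    feat = np.empty(9, dtype=np.int8)
    qv = np.empty(5, dtype=np.float64)
    for k in range(perm.shape[0]):
        i = perm[k]
        r0 = row[i]
        c0 = col[i]

        # -- perceive: indices of active features in the 3x3 window
        #    (row-major cells, channel-minor: feature = 2*cell + type) --
        cnt = 0
        cell = 0
        for dr in range(-1, 2):
            rr = r0 + dr
            if rr < 0:
                rr += m
            elif rr >= m:
                rr -= m
            for dc in range(-1, 2):
                cc = c0 + dc
                if cc < 0:
                    cc += m
                elif cc >= m:
                    cc -= m
                rt = rtype[rr, cc]
                if rt >= 0:
                    feat[cnt] = cell if type_blind else 2 * cell + rt
                    cnt += 1
                cell += 1

        # -- Q-values on the current perception --
        for a in range(5):
            s_ = np.float64(b[i, a])
            for j in range(cnt):
                s_ += W[i, a, feat[j]]
            qv[a] = s_

        # -- TD update of the pending transition (current net for both the
        #    prediction and the bootstrapped next-state maximum) --
        if learns_actions and has_prev[i]:
            qmax = qv[0]
            for a in range(1, 5):
                if qv[a] > qmax:
                    qmax = qv[a]
            ap = prev_a[i]
            pred = np.float64(b[i, ap])
            for j in range(prev_cnt[i]):
                pred += W[i, ap, prev_idx[i, j]]
            dq = prev_r[i] + gamma * qmax - pred
            step_ = np.float32(alpha * dq)
            for j in range(prev_cnt[i]):
                W[i, ap, prev_idx[i, j]] += step_
            b[i, ap] += step_
            # only the updated action's Q-value changed
            s_ = np.float64(b[i, ap])
            for j in range(cnt):
                s_ += W[i, ap, feat[j]]
            qv[ap] = s_

        # -- action selection (greedy; exploration reuses its uniform) --
        best_a = 0
        best_q = qv[0]
        for a in range(1, 5):
            if qv[a] > best_q:
                best_q = qv[a]
                best_a = a
        if eps_explore > 0.0 and u_explore[i] < eps_explore:
            best_a = int(u_explore[i] / eps_explore * 5.0)
            if best_a > 4:
                best_a = 4

        for j in range(cnt):
            prev_idx[i, j] = feat[j]
        prev_cnt[i] = cnt
        prev_a[i] = best_a
        prev_r[i] = 0.0
        has_prev[i] = True

        # -- execute --
        if best_a < 4:
            if best_a == 0:
                r0 = (r0 - 1) % m
            elif best_a == 1:
                r0 = (r0 + 1) % m
            elif best_a == 2:
                c0 = (c0 + 1) % m
            else:
                c0 = (c0 - 1) % m
            row[i] = r0
            col[i] = c0
            if move_cost > 0.0:
                e = energy[i] - move_cost
                energy[i] = e if e > 0.0 else 0.0
        else:
            rt = rtype[r0, c0]
            if rt >= 0:
                s = skill[i]
                p = s**q if rt == 0 else (1.0 - s) ** q
                if eat_rolls[i] < p:
                    if whole_cell:
                        qty[r0, c0] = 0
                    else:
                        qty[r0, c0] -= 1
                    if qty[r0, c0] == 0:
                        rtype[r0, c0] = -1
                        emptied += 1
                    energy[i] += eps_energy
                    H[i, rt] += 1
                    prev_r[i] = reward
                    if learns_skill:
                        if rt == 0:
                            s += ds
                            skill[i] = 1.0 if s > 1.0 else s
                        else:
                            s -= ds
                            skill[i] = 0.0 if s < 0.0 else s
    return emptied
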