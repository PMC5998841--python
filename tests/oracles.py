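"""Brute-force oracles shared by the unit and acceptance suites.

Each function recomputes a quantity by exhaustive enumeration or a
closed form, independently of the implementation path it checks.
"""

import itertools
import math

import numpy as np

from angiotrack import track as tk


def oracle_track_chains(endpoint, dets_per_frame, params, cfg, interface):
    """All event chains of one track by independent recursion."""
    T = len(dets_per_frame) - 1
    st0 = tk.velocity_init([endpoint], params=params)[0]

    def expand(state, k):
        if k == 0:
            return [((), (), ())]
        dets = dets_per_frame[k - 1]
        pred = tk.kf_predict(state, params)
        cands = []
        for j, z in enumerate(dets):
            g = tk.kf_gate(pred, z, params)
            if g.in_gate:
                w = tk.association_probability(g) / cfg.clutter_density
                cands.append((("obs", j), math.log(w),
                              tk.kf_update(pred, g, params)))
        if interface is not None and pred.mean[1] < cfg.b1:
            gap = interface.y(pred.mean[0]) - pred.mean[1]
            if 0.0 <= gap <= cfg.entry_band:
                w = cfg.entry_scale * tk.monolayer_probability(
                    pred.mean[1], cfg)
                cands.append((("entry",), math.log(w), None))
        cands.append((("none",), math.log(cfg.p_unobserved), pred))
        out = []
        for ev, lw, nxt in cands:
            if ev[0] == "entry":
                out.append(((ev,), (lw,), ()))
            else:
                for tail_ev, tail_lw, tail_st in expand(nxt, k - 1):
                    out.append(((ev,) + tail_ev, (lw,) + tail_lw,
                                (nxt,) + tail_st))
        return out

    chains = []
    for ev, lw, sts in expand(st0, T):
        chains.append(tk.HypothesisBranch(
            track_id=-1, events=ev, states=(st0,) + sts,
            step_logws=lw, log_lik=float(sum(lw)),
            terminated=bool(ev and ev[-1][0] == "entry")))
    return chains


def oracle_joint_argmax(per_track_chains, endpoint_frame, cfg):
    """Exhaustive product enumeration scored with the shared scorer."""
    best, best_score = None, -np.inf
    for combo in itertools.product(*per_track_chains):
        sc = tk.score_joint(list(combo), endpoint_frame, cfg)[0]
        if sc > best_score:
            best, best_score = combo, sc
    return best, best_score


def oracle_otsu_split(img_uint8):
    """Exhaustive 256-threshold between-class-variance maximiser."""
    hist = np.bincount(img_uint8.ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    levels = np.arange(256)
    best_t, best_v = 0, -1.0
    for t in range(1, 256):
        w0, w1 = p[:t].sum(), p[t:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (levels[:t] * p[:t]).sum() / w0
        mu1 = (levels[t:] * p[t:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t


def oracle_min_cost_permutation(cost):
    """Minimal-cost one-to-one assignment by full permutation scan."""
    n = len(cost)
    best, best_c = None, np.inf
    for perm in itertools.permutations(range(n)):
        c = sum(cost[i, p] for i, p in enumerate(perm))
        if c < best_c:
            best, best_c = perm, c
    return best, best_c
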