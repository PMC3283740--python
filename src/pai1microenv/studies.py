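"""Reproducibility studies: the package's headline simulation claims, each
recomputed from scratch at a configurable scale.

Each study runs the pipeline under its default ("study") conditions and
returns summary numbers: mass-ledger closure, peripheral heterogeneity of
stochastic vs deterministic growth, the invagination-concentration
association, the bistable window and hysteresis loop, hiving cycles, the
minority-amoeboid property, brute-force oracle equivalence of the core
operations, ground-truth recovery of the generators, and permutation-test
calibration.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

from .abm import ABMRates, make_world, run_abm, run_single_cell_spot
from .ca import CARates, paired_disk_control, periphery_values, run_ca
from .errors import DomainError
from .imaging import ChannelImage, colocalization_percent, z_profile
from .lattice import Grid, OccupancyMask, ScalarField, diffuse, neighbors
from .spatial import (
    PeripheryProfile,
    boundary_curvature,
    boundary_set,
    default_spot_threshold,
    detect_spots,
    extract_periphery,
    heterogeneity_metrics,
    invagination_association,
)
from .switch import (
    SwitchParams,
    bistable_window,
    fit_thresholds,
    steady_states,
    sweep_hysteresis,
)
from .synth import ShapeSpec, make_coloc_pair, make_morph_timecourse, make_tumor_mask

__all__ = [
    "mass_conservation_study",
    "heterogeneity_study",
    "invagination_study",
    "hysteresis_study",
    "hiving_study",
    "minority_amoeboid_study",
    "oracle_equivalence_study",
    "recovery_study",
    "permutation_calibration_study",
]


def _child_seed(base: int, k: int) -> int:
    return int((base * 1_000_003 + k) % 2**31)


def mass_conservation_study(seed: int = 0, n_ca: int = 35, n_abm: int = 15) -> dict:
    """Max relative mass-ledger error over random CA and ABM runs.

    CA ledger: cumulative secreted = soluble + bound_active + bound_latent.
    ABM ledger additionally includes the consumed (internalized) pool.
    """
    rng = np.random.default_rng(seed)
    err_ca = 0.0
    for k in range(n_ca):
        rates = CARates(
            sigma=float(rng.uniform(0.2, 2.0)),
            D=float(rng.uniform(0.05, 0.25)),
            k_on=float(rng.uniform(0.05, 0.8)),
            p_div=float(rng.uniform(0.05, 0.3)),
        )
        res = run_ca(
            rates, grid=Grid(48, 48), seed=_child_seed(seed, k),
            checkpoints=(int(rng.integers(50, 200)),), record_log=False,
        )
        err_ca = max(err_ca, res.summary["mass_balance_rel_error"])
    err_abm = 0.0
    for k in range(n_abm):
        rates = ABMRates(
            sigma=float(rng.uniform(0.2, 2.0)),
            k_int=float(rng.uniform(0.1, 1.0)),
            p_div_mes=float(rng.uniform(0.05, 0.2)),
        )
        res = run_abm(
            rates=rates, grid=Grid(48, 48), ticks=int(rng.integers(60, 120)),
            seed=_child_seed(seed, 1000 + k),
        )
        err_abm = max(err_abm, res.summary["mass_balance_rel_error"])
    return {"max_rel_error_ca": err_ca, "max_rel_error_abm": err_abm,
            "n_runs": n_ca + n_abm}


def heterogeneity_study(seed: int = 0, n_seeds: int = 50) -> dict:
    """Stochastic-growth peripheral CV vs matched deterministic-disk control.

    For each seed, one CA run to the 10/100/500-cell checkpoints and one
    disk-control replaying its cell-count trajectory. Reports the fraction of
    seed pairs where the stochastic CV exceeds the control CV at the 500-cell
    checkpoint, and the fraction of seeds with at least one spot (threshold =
    theta_up of the default switch) at 500 cells.
    """
    rates = CARates()
    thr = default_spot_threshold()
    wins = spot_present = 0
    cvs, cvs_ctrl = [], []
    for k in range(n_seeds):
        res = run_ca(rates, grid=Grid(64, 64), seed=_child_seed(seed, k),
                     checkpoints=(10, 100, 500))
        cp = res.checkpoints[-1]
        pv = periphery_values(cp.mask, cp.bound)
        ctrl = paired_disk_control(res, rates)
        pvc = periphery_values(
            ctrl.mask,
            ScalarField(ctrl.mask.grid, ctrl.matrix.bound_active + ctrl.matrix.bound_latent),
        )
        cv = float(pv.std() / pv.mean())
        cv_ctrl = float(pvc.std() / pvc.mean())
        cvs.append(cv)
        cvs_ctrl.append(cv_ctrl)
        wins += cv > cv_ctrl
        spot_present += pv.max() >= thr
    return {
        "n_seeds": n_seeds,
        "cv_win_fraction": wins / n_seeds,
        "spot_presence_fraction": spot_present / n_seeds,
        "mean_cv_stochastic": float(np.mean(cvs)),
        "mean_cv_disk": float(np.mean(cvs_ctrl)),
        "spot_threshold": thr,
    }


def invagination_study(seed: int = 0, n_pairs: int = 30) -> dict:
    """Concentration-invagination association: 4-lobed vs disk seed masks.

    Each seed mask (radius 16; lobed: 4 lobes, depth 0.5) grows stochastically
    for 50 ticks at p_div = 0.005 — enough to perturb the geometry per seed
    without filling in the invaginations — then the rank association between
    peripheral bound PAI-1 and negated curvature is compared within the pair.
    One-sided sign test across the pairing.
    """
    g = Grid(56, 56)
    rates = CARates(p_div=0.005)
    wins = valid = 0
    for k in range(n_pairs):
        s = _child_seed(seed, k)
        corr = {}
        for kind, nl, depth in (("lobed", 4, 0.5), ("disk", 0, 0.0)):
            mask, _ = make_tumor_mask(ShapeSpec(kind, 16, nl, depth), grid=g)
            res = run_ca(rates, initial_mask=mask, growth="stochastic",
                         checkpoints=None, ticks=50, seed=s, record_log=False)
            prof = extract_periphery(res.mask, ScalarField(g, res.matrix.bound_active))
            boundary_curvature(prof, window=7)
            corr[kind] = invagination_association(prof, seed=s, window=7)["correlation"]
        valid += 1
        wins += corr["lobed"] > corr["disk"]
    p = float(sstats.binomtest(wins, valid, 0.5, alternative="greater").pvalue)
    return {"n_pairs": valid, "lobed_wins": wins, "sign_test_p": p}


def nullcline_fixed_points(C: float, p: SwitchParams, n_grid: int = 2000) -> list:
    """Closed-form nullcline oracle for the switch fixed points.

    On the dI/dt = 0 nullcline, I(P) is explicit; substituting into
    dP/dt = 0 leaves a 1D root problem solved by scanning an ``n_grid``-point
    P grid (the same resolution in I is implied by the closed form) for sign
    changes and bisecting each to ~1e-12. Returns stable (I, P) pairs sorted
    by decreasing P.
    """
    hp = C**p.h / (p.K**p.h + C**p.h)

    def I_of(P):
        return p.alpha_I * (1.0 - hp) / (p.mu * (1.0 + P**2))

    def G(P):
        return p.alpha_P * hp / (1.0 + I_of(P) ** 2) - p.mu * P

    Ps = np.linspace(0.0, p.alpha_P / p.mu + 1.0, n_grid)
    vals = G(Ps)
    out = []
    for i in np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:])):
        lo, hi = Ps[i], Ps[i + 1]
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if np.sign(G(mid)) == np.sign(G(lo)):
                lo = mid
            else:
                hi = mid
        P = 0.5 * (lo + hi)
        I = float(I_of(P))
        dfdP = p.alpha_I * (1 - hp) * (-2 * P) / (1 + P**2) ** 2
        dgdI = p.alpha_P * hp * (-2 * I) / (1 + I**2) ** 2
        if dfdP * dgdI < p.mu**2:
            out.append((I, float(P)))
    return sorted(out, key=lambda s: -s[1])


def hysteresis_study(seed: int = 0, sweep_rate_factor: float = 2000.0) -> dict:
    """Bistable window, hysteresis loop, and nullcline-oracle agreement.

    The static window is located by scanning steady_states over C; the loop by
    a slow sweep (rate ``sweep_rate_factor``/mu; slower than the quasi-static
    minimum to shrink the delayed-bifurcation lag). Agreement is the maximum
    distance between loop thresholds and window edges; the window is always
    nested inside the loop. The relaxation fixed points are compared to the
    closed-form nullcline oracle on a 2000-point bisection grid.
    """
    p = SwitchParams()
    lo, hi = bistable_window(p, n_scan=400)
    loop = sweep_hysteresis(p, c_max=2.5 * p.K, rate=sweep_rate_factor / p.mu)
    nested = loop.theta_down <= lo <= hi <= loop.theta_up
    max_dev = 0.0
    for C in np.linspace(0.0, 2.0 * p.K, 21):
        ours = steady_states(float(C), p)
        oracle = nullcline_fixed_points(float(C), p, n_grid=2000)
        if len(ours) != len(oracle):
            max_dev = np.inf
            continue
        for s, (I, P) in zip(ours, oracle):
            max_dev = max(max_dev, abs(s.I - I), abs(s.P - P))
    return {
        "window_low": lo,
        "window_high": hi,
        "theta_up": loop.theta_up,
        "theta_down": loop.theta_down,
        "loop_width": loop.width,
        "window_nested_in_loop": bool(nested),
        "threshold_window_max_gap_over_K": max(loop.theta_up - hi, lo - loop.theta_down) / p.K,
        "nullcline_oracle_max_dev": max_dev,
    }


def hiving_study(seed: int = 0, n_seeds: int = 100) -> dict:
    """Hiving cycles on a pre-loaded spot: MAT -> consume -> AMT ordering,
    and the absence of reversal when consumption is disabled."""
    cycles = no_reversal = 0
    for k in range(n_seeds):
        s = _child_seed(seed, k)
        res = run_single_cell_spot(seed=s)
        ev = [r["event"] for r in res.log.records]
        try:
            i_mat = ev.index("flip_MAT")
            i_amt = ev.index("flip_AMT")
            consumes = [i for i, e in enumerate(ev) if e == "consume"]
            if consumes and i_mat < consumes[0] < i_amt:
                cycles += 1
        except ValueError:
            pass
        res0 = run_single_cell_spot(k_int=0.0, seed=s)
        ev0 = [r["event"] for r in res0.log.records]
        if "flip_MAT" in ev0 and "flip_AMT" not in ev0:
            no_reversal += 1
    return {
        "n_seeds": n_seeds,
        "cycle_fraction": cycles / n_seeds,
        "no_reversal_fraction": no_reversal / n_seeds,
    }


def minority_amoeboid_study(seed: int = 0, n_runs: int = 20, ticks: int = 250) -> dict:
    """Instantaneous amoeboid fraction across default-parameter ABM runs."""
    max_frac = 0.0
    finals = []
    for k in range(n_runs):
        res = run_abm(ticks=ticks, seed=_child_seed(seed, k))
        max_frac = max(max_frac, float(res.amoeboid_fraction.max()))
        finals.append(float(res.amoeboid_fraction[-1]))
    return {
        "n_runs": n_runs,
        "max_amoeboid_fraction": max_frac,
        "mean_final_amoeboid_fraction": float(np.mean(finals)),
    }


def oracle_equivalence_study(seed: int = 0, n_instances: int = 100) -> dict:
    """Brute-force equivalence of the core lattice/stat operations.

    Each operation is checked against an independent loop/enumeration oracle
    on ``n_instances`` random small instances; the returned values are
    mismatch counts (0 = exact agreement everywhere).
    """
    from .abm import move as abm_move
    from .ca import grow_tumor_step

    rng = np.random.default_rng(seed)
    mism = dict.fromkeys(
        ["diffusion", "neighbors", "boundary", "spots", "movement", "colocalization"], 0
    )

    for _ in range(n_instances):
        # diffusion stencil vs loop oracle
        h, w = int(rng.integers(3, 9)), int(rng.integers(3, 9))
        g = Grid(w, h)
        vals = rng.uniform(0, 5, g.shape)
        a = float(rng.uniform(0.01, 0.25))
        out = diffuse(ScalarField(g, vals), a, 1.0).values
        oracle = vals.copy()
        for r in range(h):
            for c in range(w):
                nb = [vals[rr, cc] for rr, cc in ((r-1, c), (r+1, c), (r, c-1), (r, c+1))
                      if 0 <= rr < h and 0 <= cc < w]
                oracle[r, c] = vals[r, c] + a * (sum(nb) - len(nb) * vals[r, c])
        if not np.allclose(out, oracle, rtol=1e-10, atol=1e-12):
            mism["diffusion"] += 1

        # neighbors vs |dx|,|dy| enumeration
        site = (int(rng.integers(h)), int(rng.integers(w)))
        for scheme, lim in (("von_neumann", 1), ("moore", 2)):
            brute = {(site[0]+dr, site[1]+dc)
                     for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                     if (dr, dc) != (0, 0) and abs(dr)+abs(dc) <= lim
                     and 0 <= site[0]+dr < h and 0 <= site[1]+dc < w}
            if set(neighbors(g, site, scheme)) != brute:
                mism["neighbors"] += 1

        # boundary extraction vs set comprehension
        gb = Grid(14, 14)
        mask = OccupancyMask.single(gb)
        target = int(rng.integers(2, 25))
        while mask.count() < target:
            mask, _ = grow_tumor_step(mask, 1.0, rng, max_new=target - mask.count())
        brute = {(r, c) for r in range(gb.height) for c in range(gb.width)
                 if not mask.occupied[r, c]
                 and any(0 <= r+dr < gb.height and 0 <= c+dc < gb.width
                         and mask.occupied[r+dr, c+dc]
                         for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)))}
        if boundary_set(mask) != brute:
            mism["boundary"] += 1

        # spot detection vs circular run-length scan
        n = int(rng.integers(8, 40))
        conc = rng.uniform(0, 4, n)
        thr = float(rng.uniform(0.5, 3.5))
        prof = PeripheryProfile([(0, i) for i in range(n)], conc)
        got = [(sp.start, sp.length) for sp in detect_spots(prof, thr).spots]
        above = conc >= thr
        if above.all():
            brute_runs = [(0, n)]
        else:
            brute_runs = []
            for i in range(n):
                if above[i] and not above[(i-1) % n]:
                    length = 0
                    while above[(i+length) % n]:
                        length += 1
                    brute_runs.append((i, length))
            brute_runs.sort()
        if got != brute_runs:
            mism["spots"] += 1

        # greedy amoeboid movement vs argmax oracle (distinct field values)
        gm = Grid(9, 9)
        bound = rng.permutation(81).astype(float).reshape(9, 9)
        pos = (int(rng.integers(1, 8)), int(rng.integers(1, 8)))
        m = OccupancyMask.empty(gm)
        m.occupied[pos] = True
        world = make_world(m)
        agent = world.agents[0]
        agent.I, agent.P = 0.0, 5.0  # amoeboid
        world.matrix.bound_active[:] = bound
        abm_move(agent, world, ABMRates(speed_amoeboid=1.0), rng)
        cands = [(pos[0]+dr, pos[1]+dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
        expect = max(cands, key=lambda s: bound[s])
        if agent.position != expect:
            mism["movement"] += 1

        # colocalization counting vs double loop
        px1 = rng.uniform(0, 1000, (8, 8))
        px2 = rng.uniform(0, 1000, (8, 8))
        res = colocalization_percent(ChannelImage(px1), ChannelImage(px2))
        n1 = n2 = nc = 0
        for r in range(8):
            for c in range(8):
                a1 = 0.0 if px1[r, c] < 25 else px1[r, c]
                a2 = 0.0 if px2[r, c] < 25 else px2[r, c]
                p1, p2 = a1 >= 100, a2 >= 100
                n1 += p1
                n2 += p2
                nc += p1 and p2
        if (res.n_pos_ch1, res.n_pos_ch2, res.n_coloc) != (n1, n2, nc):
            mism["colocalization"] += 1

    mism["n_instances"] = n_instances
    return mism


def recovery_study(seed: int = 0, n_fits: int = 20) -> dict:
    """Ground-truth recovery: colocalization %, z-stack basal fraction, and
    switch-threshold recovery from noisy morphology time-courses."""
    ch1, ch2, _ = make_coloc_pair(f_coloc=0.30, n_pos=10_000, seed=_child_seed(seed, 1))
    coloc = colocalization_percent(ch1, ch2)

    from .synth import make_zstack

    stack, _ = make_zstack(basal_ratio=3.0, n_pos=10_000, seed=_child_seed(seed, 2))
    zres = z_profile(stack)

    true = SwitchParams()
    ref = sweep_hysteresis(true, c_max=4.0 * true.K)
    max_err = 0.0
    for k in range(n_fits):
        df, _ = make_morph_timecourse(true, n_cells=500, seed=_child_seed(seed, 100 + k))
        fit = fit_thresholds(df["time"].values, df["blebbing"].values,
                             df["C"].values, true)
        max_err = max(
            max_err,
            abs(fit.theta_up - ref.theta_up) / ref.theta_up,
            abs(fit.theta_down - ref.theta_down) / ref.theta_down,
        )
    return {
        "coloc_pct_ch1": coloc.pct_ch1,
        "coloc_pct_ch2": coloc.pct_ch2,
        "zstack_basal_fraction": zres["basal_fraction"],
        "threshold_recovery_max_rel_error": max_err,
        "n_fits": n_fits,
    }


def permutation_calibration_study(seed: int = 0, n_rep: int = 200) -> dict:
    """Type-I error of the cyclic-shift permutation test at nominal 0.05.

    Concentration profiles are independent lognormal noise laid on the
    periphery of a 4-lobed mask (realistic curvature sequence); under this
    null the association p-values should be uniform.
    """
    mask, _ = make_tumor_mask(ShapeSpec("lobed", 16, 4, 0.5))
    base = extract_periphery(mask, ScalarField.zeros(mask.grid))
    boundary_curvature(base, window=5)
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_rep):
        prof = PeripheryProfile(
            base.boundary_sites, rng.lognormal(0, 1, len(base)), curvature=base.curvature
        )
        rej += invagination_association(prof, seed=int(rng.integers(2**31)))["p_value"] < 0.05
    return {"n_replicates": n_rep, "type_one_error": rej / n_rep}
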