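#!/usr/bin/env python
"""Dwell-time survival, flow-out retention, exchange and FRAP kinetics.

Four kinetic analyses sharing the mono-exponential fitting layer:

1. membrane dwell times inside vs outside GEF areas under buffer flow-out
   with a dimeric effector (programmed 1.4-fold retention inside);
2. the GEF-saturated nucleotide-exchange trace (loss of FRET), whose
   maximal rate plateaus near 2e-4 s⁻¹;
3. a FRAP recovery trace (mono-exponential growth) reporting bilayer
   fluidity;
4. a photoactivation decay giving the half-time of pool disappearance.
"""

import argparse
import json
from pathlib import Path

from rhopattern.kinetics import (
    dwell_half_time_ratio,
    fit_monoexp,
    fit_survival,
    survival_curve,
)
from rhopattern.synthetic import SimConfig, simulate_decay_trace, simulate_tracks


def observed_dwell_fit(k_off, seed):
    cfg = SimConfig(
        fov_width=20, fov_height=20, n_frames=7000, landing_rate=0.05,
        diffusion_coeff=0.3, dissociation_rate=k_off, colabel_fraction=0,
        seed=seed,
    )
    _, _, gt = simulate_tracks(cfg)
    tr = gt.tracks[~gt.tracks.left_fov]
    dwells = (tr.death_frame - tr.birth_frame + 1) * cfg.frame_interval
    censored = tr.death_frame == cfg.n_frames - 1
    curve = survival_curve(dwells.to_numpy(), censored.to_numpy())
    return fit_survival(curve), curve


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    report = {}

    k_out = 2.0
    fit_in, c_in = observed_dwell_fit(k_out / 1.4, args.seed)
    fit_out, c_out = observed_dwell_fit(k_out, args.seed + 1)
    ratio, se = dwell_half_time_ratio(fit_in, fit_out)
    report["dwell"] = dict(
        t_half_in_s=fit_in.t_half, t_half_out_s=fit_out.t_half,
        fold_change=ratio, se=se, n=c_in.n_total + c_out.n_total,
    )
    print(f"flow-out retention: t½(in) = {fit_in.t_half:.3f} s, "
          f"t½(out) = {fit_out.t_half:.3f} s -> {ratio:.2f}-fold longer inside "
          f"(programmed 1.4-fold)")

    t, y = simulate_decay_trace(1.0, 2e-4, 0.25, 5.0, 1000, noise_sd=0.01,
                                seed=args.seed + 2)
    fx = fit_monoexp(t, y, model="decay")
    report["exchange"] = dict(rate_per_s=fx.rate, se=fx.se_rate, r2=fx.r_squared)
    print(f"saturated exchange rate: {fx.rate:.2e} s⁻¹ (truth 2.0e-04)")

    t, y = simulate_decay_trace(0.8, 0.15, 0.2, 0.5, 240, noise_sd=0.01,
                                mode="growth", seed=args.seed + 3)
    frap = fit_monoexp(t, y, model="growth")
    report["frap"] = dict(rate_per_s=frap.rate, t_half_s=frap.t_half)
    print(f"FRAP recovery: k = {frap.rate:.3f} s⁻¹, t½ = {frap.t_half:.1f} s "
          f"(fluid bilayer)")

    t, y = simulate_decay_trace(1.0, 0.01, 0.05, 2.0, 300, noise_sd=0.01,
                                seed=args.seed + 4)
    pa = fit_monoexp(t, y, model="decay")
    report["photoactivation"] = dict(rate_per_s=pa.rate, t_half_s=pa.t_half)
    print(f"photoactivated pool disappearance: t½ = {pa.t_half:.1f} s "
          f"(truth ln2/0.01 = 69.3 s)")

    (args.out / "kinetics.json").write_text(json.dumps(report, indent=1))
    print(f"fit report written to {args.out / 'kinetics.json'}")


if __name__ == "__main__":
    main()
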