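"""Hierarchical ABC test of simultaneous vs nonsimultaneous divergence.

Builds one prior-predictive reference table for the 8-pair layout, then
rejection-samples the posteriors of both synthetic studies (simultaneous and
staggered truth). Reports the posterior over the number of divergence events
Ψ, the mean divergence time E(τ), the dispersion index Ω = Var(τ)/E(τ), and
the Bayes factor for Ω ≤ 0.01 vs Ω > 0.01. Posterior reports go to
results/synthetic_study/<study>/habc_posterior.json.
"""

import argparse
import json
import math
from pathlib import Path


from beringia import habc, pipeline
from beringia.io_manifest import read_manifest

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=11)
parser.add_argument("--reps", type=int, default=100_000)
parser.add_argument("--tolerance", type=float, default=0.001)
parser.add_argument("--theta-upper", type=float, default=0.2,
                    help="reference mutation scale (the generator's truth scale)")
args = parser.parse_args()

base = Path("results/synthetic_study")
studies = {s: read_manifest(base / s / "manifest.tsv") for s in ("simultaneous", "staggered")}
layout = [(p.deme_a.n, p.deme_b.n, p.length) for p in next(iter(studies.values()))]

cfg = habc.HabcConfig(
    theta_upper=args.theta_upper, n_reps=args.reps, tolerance=args.tolerance,
    seed=args.seed,
)
print(f"building reference table: {args.reps} replicates, {len(layout)} pairs ...")
table = habc.build_reference_table(layout, cfg)
prior_omega = habc.prior_omega_samples(cfg, len(layout))

for name, manifest in studies.items():
    observed = pipeline.observed_vector(list(manifest))
    posterior = habc.rejection_sample(observed, table)
    report = posterior.summary()
    bf = habc.bayes_factor_omega(posterior, prior_omega)
    report["bayes_factor_omega_le_0.01"] = bf if math.isfinite(bf) else "inf"
    with open(base / name / "habc_posterior.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    truth = json.loads((base / name / "truth.json").read_text())
    print(f"\n{name} study (true psi = {truth['psi_true']}):")
    print(f"  psi posterior mode = {report['psi_mode']}, "
          f"P(psi=1) = {report['psi_probs'][0]:.3f}")
    print(f"  E(tau) mean = {report['e_tau_mean']:.4f}; "
          f"omega median = {report['omega_median']:.4f}; "
          f"P(omega > 0.01) = {report['p_omega_gt_0.01']:.3f}")
    print(f"  Bayes factor (omega <= 0.01 vs > 0.01) = {report['bayes_factor_omega_le_0.01']}")

print(
    "\nReading: a posterior concentrated at psi = 1 with omega near zero and a "
    "Bayes factor well above 1 supports one shared vicariance event; dispersed "
    "omega mass with a Bayes factor near zero supports staggered divergence."
)
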