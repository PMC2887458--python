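"""Fit optimal force constants (OFCs) to a toy NMR-style ensemble.

Builds a synthetic 25-residue ensemble with a known interaction network,
writes it as a multi-MODEL PDB, then runs the full pipeline: read,
superpose, scalar covariance, entropy-maximization fit on the 10 Å
contact topology, and reports how well the fitted network reproduces
the observed covariances.
"""

import tempfile
from pathlib import Path

import ofcnet as oc

# --- build a toy ensemble from a known ground-truth network -----------
spec = oc.SyntheticNetworkSpec(n=25, seed=7)
K_true, _ = oc.generate_network(spec)
ens_out = oc.sample_ensemble(K_true, m=200, seed=8, amplitude=0.4)
pdb = Path(tempfile.gettempdir()) / "toy_ensemble.pdb"
oc.write_toy_pdb(ens_out, pdb)

# --- the production pipeline ------------------------------------------
ens = oc.read_multimodel_structure(pdb)
ens, mean = oc.superpose_ensemble(ens)
cov = oc.scalar_covariance(ens)
topo = oc.contact_topology(mean, cutoff=10.0)
pi = oc.ConstraintSet.from_pairs(topo.edges)
K = oc.optimize_K(cov, pi, oc.OptimizerSettings(tolerance=0.01))

table = oc.force_constant_table(K, mean)
table = oc.normalize_ofc(table)
agree = oc.covariance_agreement(cov, oc.covariance_from_K(K.K), topo)

print(f"ensemble: m={ens.n_models} models, N={ens.n_residues} residues")
print(f"contacts within 10 A: {topo.n_edges} pairs")
print(f"fit converged in {K.n_steps} steps")
print(f"mean |gamma| after normalization: {table['gamma'].abs().mean():.3f}")
print(f"cc(MSF)            = {agree['msf']:.3f}")
print(f"cc(interacting)    = {agree['interacting']:.3f}")
print(f"cc(non-interacting)= {agree['non_interacting']:.3f}")
print(f"cc(all off-diag)   = {agree['all']:.3f}")
print()
print("The fitted network reproduces constrained covariances (MSFs and")
print("contacting pairs) exactly by construction (cc = 1.000); agreement")
print("on non-contacting pairs is inherited, not imposed.")
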