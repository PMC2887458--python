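"""Compare GNM variants against observed covariances on a toy helix.

The "observed" covariance here is generated from a modified-GNM network
(inverse-square base, bonded x10, second-neighbor x(-5), H-bond x10) on
an ideal helix, so the exercise shows how each of the ten edge-weighting
recipes — uniform (U) or inverse-square (D) base with bonded (g1),
second-neighbor (g2) and hydrogen-bond (HB) factors — scores when the
underlying physics actually contains those ingredients.
"""

import ofcnet as oc

ens = oc.ideal_helix_ensemble(35, m=2)
anns = oc.assign_hbonds_internal(ens)
mean = oc.MeanStructure(ens.model_coords[0])
topo = oc.contact_topology(mean, cutoff=10.0)

truth = oc.build_mgnm(mean, topo, anns, oc.model_variant("mGNM"))
cov_obs = oc.gnm_covariance(truth)

print(f"{'variant':<20}{'cc(MSF)':>9}{'cc(offdiag)':>13}")
for name in ("U", "D", "U+g1", "D+g1", "U+g1+g2", "D+g1+g2",
             "U+g1+HB", "D+g1+HB", "U+g1+g2+HB", "D+g1+g2+HB"):
    net = oc.build_mgnm(mean, topo, anns, oc.model_variant(name))
    pred = oc.gnm_covariance(net)
    agree = oc.covariance_agreement(cov_obs, pred, topo)
    tag = " (GNM)" if name == "U" else (" (mGNM)" if name == "D+g1+g2+HB"
                                        else "")
    print(f"{name + tag:<20}{agree['msf']:>9.3f}{agree['all']:>13.3f}")

print()
print("The mGNM row reaches 1.000 because it is the generating model;")
print("recipes sharing more of its ingredients (bonded amplification,")
print("negative second neighbors, H-bond weighting) score higher.")
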