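"""Spatial niche-proximity analysis of simulated bone-marrow sections.

Places 50 reference niche cells and 1000 background nuclei uniformly in a
1 x 1 mm field, draws 200 "leukemic" query cells attracted to the niche
(acceptance probability exp(-d/25um)), and tests whether query cells sit
closer to the niche than matched random cells using two-sample KS and
Anderson-Darling statistics on nearest-neighbour distance ECDFs.
"""

import xenotrace as xt

cfg = xt.SimulationConfig(seed=3, n_query=200, attraction_scale=25.0)
pattern, _ = xt.simulate_points(cfg)
report = xt.proximity_test(pattern, n_perm=9999, seed=4)

print(f"query cells:      {report['n_query']} (median distance to niche "
      f"{report['median_query']:.1f} um)")
print(f"background cells: {report['n_background_used']} (median distance "
      f"{report['median_background']:.1f} um)")
print(f"median shift: {report['median_shift']:+.1f} um (negative = query closer)")
ks, ad = report["ks"], report["ad"]
print(f"\nKS:  D = {ks['statistic']:.3f}, p_perm = {ks['p_permutation']:.2e}, "
      f"p_asymptotic = {ks['p_asymptotic']:.2e}")
print(f"AD:  A2 = {ad['statistic']:.2f}, p_perm = {ad['p_permutation']:.2e}")

null_cfg = xt.SimulationConfig(seed=3, attraction_scale=None)
null_pattern, _ = xt.simulate_points(null_cfg)
null_report = xt.proximity_test(null_pattern, n_perm=9999, seed=4)
print(f"\nsame field with uniformly placed query cells (negative control): "
      f"KS p_perm = {null_report['ks']['p_permutation']:.2f}")
print("A small p for the attracted pattern and a large one for the uniform")
print("pattern is the Fig-7-style signature of non-random niche proximity.")
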