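"""Filter covariate layers for multicollinearity, per modelling region.

The variance inflation factor VIF_j = 1/(1 - R^2_j) measures how well layer j
is explained by the others; layers are dropped greedily until all VIFs fall at
or below 3. The synthetic world plants one near-collinear layer on purpose.
"""

import ortmap as om

world = om.simulate_world(om.WorldConfig(), seed=7)
reports = om.vif_filter_by_region(world.covariates, threshold=3.0)

for region, rep in reports.items():
    print(f"region {region}: removed {rep.removed or 'nothing'}; "
          f"retained {len(rep.retained)} layers")
    worst = max(rep.vif, key=rep.vif.get)
    print(f"  largest remaining VIF: {rep.vif[worst]:.2f} ({worst}) <= 3 threshold")
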