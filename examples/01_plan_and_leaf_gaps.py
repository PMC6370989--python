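"""Generate a synthetic VMAT plan, read it back, and summarize leaf gaps.

Builds the 160-control-point water-phantom VMAT fixture, parses the
RT Plan, and prints the leaf-pair distance statistics: the fraction of
in-field leaf pairs closer than 10 mm is the plan feature that predicts
where rounded-tip transmission makes a planning system overestimate
dose.
"""

import tempfile
from pathlib import Path

from mlcdose.mlc import leaf_pair_distance_stats
from mlcdose.rt_io import generate_fixtures, read_plan

with tempfile.TemporaryDirectory() as td:
    paths = generate_fixtures("water_vmat", Path(td), seed=1)
    plan = read_plan(paths["plan"])

print(f"plan '{plan.plan_label}': {plan.technique}, "
      f"{plan.n_control_points()} control points, {plan.total_mu} MU")
stats = leaf_pair_distance_stats(plan, threshold=10.0)
print(f"leaf-pair distance matrix: {stats.distances.shape} "
      f"(control points x pairs)")
print(f"min/median/max in-field tip gap: "
      f"{stats.distances[stats.in_field].min():.1f} / "
      f"{float(__import__('numpy').median(stats.distances[stats.in_field])):.1f} / "
      f"{stats.distances[stats.in_field].max():.1f} mm")
print(f"LP<10mm in-field ratio: {stats.ratio:.3f}")
print("A high ratio means many nearly-closed pairs sweep the field, so")
print("rounded-tip leakage contributes a larger share of the dose there.")
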