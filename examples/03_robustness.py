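"""How much observation effort does a stable network need?

Networks are rebuilt from cumulative monthly datasets; the mean degree
trajectory flattens once few new edges appear, and the bootstrap uncertainty
index (width of the 95% interval under recipient reshuffling) shrinks. The
stabilization effort is the cumulative observation time after which every
subsequent relative change stays below 5%.
"""

import warnings

import focalscan as fs
from focalscan.robustness import (
    cumulative_networks,
    metric_trajectory,
    stabilization_effort,
    uncertainty_trajectory,
)

warnings.filterwarnings("ignore")

config = fs.ScenarioConfig(
    groups=[fs.GroupConfig(name="Dam", size=15, style="tolerant_bonnet",
                           retention=1.0, months=10)],
    seed=3,
)
group = fs.make_scenario(config).groups["Dam"]

for method, sessions, unit in (("FAS", group.focal_sessions, "h"),
                               ("ABS", group.scan_sessions, "sessions")):
    events = [e for e in group.events
              if e.method.value == method and e.behaviour.value == "grooming"]
    pnets = cumulative_networks(events, group.roster, sessions, "grooming", method)
    curve = metric_trajectory(pnets, "degree")
    widths = uncertainty_trajectory(events, group.roster, sessions, "grooming",
                                    method, "degree", B=200, seed=5)
    effort, ok = stabilization_effort(curve)
    print(f"\n{method}: cumulative effort ({unit}) -> mean degree [uncertainty width]")
    for k in range(len(curve.value)):
        print(f"  month {k + 1:2d}: {curve.cumulative_effort[k]:7.1f} {unit:8s} "
              f"{curve.value[k]:.3f}  [{widths[k].width:.3f}]")
    print(f"  stabilized after {effort:.1f} {unit}" if ok
          else "  did not stabilize in this window")

print("\nThe scan protocol reaches a stable mean degree with far less "
      "observation time than focal follows, because every session informs "
      "all visible dyads at once.")
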