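"""Simulate a small macaque study and write it as CSV.

Two groups with different social styles are observed for three months with
both protocols: 10-minute focal follows (two per subject per week) and
twelve 10-minute scan sessions per week. The printed counts show the
protocols' differing yield: scans record events among every visible dyad,
follows only events involving the focal animal.
"""

from collections import Counter

import focalscan as fs

config = fs.ScenarioConfig(
    groups=[
        fs.GroupConfig(name="Temple", size=15, style="despotic_rhesus",
                       retention=0.85, months=3),
        fs.GroupConfig(name="Dam", size=12, style="tolerant_bonnet",
                       retention=0.95, months=3),
    ],
    seed=11,
)
scenario = fs.make_scenario(config)
scenario.write_csv("example_dataset")

for name, group in scenario.groups.items():
    counts = Counter((e.behaviour.value, e.method.value) for e in group.events)
    print(f"\ngroup {name} ({group.config.style}): "
          f"{len(group.focal_sessions)} follows, {len(group.scan_sessions)} scans")
    for behaviour in ("grooming", "huddling", "aggression"):
        fas = counts.get((behaviour, "FAS"), 0)
        abs_ = counts.get((behaviour, "ABS"), 0)
        print(f"  {behaviour:10s}  FAS {fas:4d}   ABS {abs_:4d}")

print("\nThe despotic group huddles rarely and aggresses more; the scan "
      "protocol (ABS) collects several times more dyadic interactions per "
      "observation hour than focal follows.")
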