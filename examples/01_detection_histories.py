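"""Build per-station detection histories from raw camera-trap records.

Constructs a handful of deployments and photo records, collapses them to
detection-day counts with effort, and prints naive occupancy — the
uncorrected fraction of stations with at least one detection.
"""

import datetime as dt

from commoccu import (
    DeploymentRecord,
    DetectionRecord,
    assign_season,
    build_detection_dataset,
    naive_occupancy,
)

start = dt.date(2006, 11, 1)
deployments = [
    DeploymentRecord(f"st{j}", x=float(j), y=0.0, start_date=start,
                     end_date=start + dt.timedelta(days=20 + 5 * j),
                     on_road=j % 2)
    for j in range(4)
]

photos = [
    DetectionRecord("st0", "spotted_hyena", dt.datetime(2006, 11, 3, 2, 10)),
    DetectionRecord("st0", "spotted_hyena", dt.datetime(2006, 11, 3, 2, 12)),  # same night
    DetectionRecord("st0", "genet", dt.datetime(2006, 11, 5, 23, 40)),
    DetectionRecord("st2", "spotted_hyena", dt.datetime(2006, 11, 9, 4, 0)),
    DetectionRecord("st3", "genet", dt.datetime(2006, 11, 20, 1, 30)),
]

data = build_detection_dataset(photos, deployments)
print("species x stations:", data.y.shape)
print("trap-days per station:", data.k.tolist())
print("detection-day counts:\n", data.y)
print("seasons (1 = dry, from median date):",
      [assign_season(d) for d in deployments])
print(naive_occupancy(data).to_string())
print("Naive occupancy counts a station as occupied only when the species "
      "was photographed there, so it underestimates true occurrence "
      "whenever per-day detection probability is below one.")
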