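#!/usr/bin/env python
"""Express landmarks in the average scapula frame and extract orientations.

Reads results/landmarks.csv (from 01_simulate.py), builds the per-scapula
average frame, rotates into the thorax frame at the published resting pose
(41.1, 5.4, 13.5 deg) and decomposes each digitization's scapula frame into
YXZ Euler angles.  Writes results/coordinates.csv and
results/orientations.csv and prints the spread of each angle.
"""

from pathlib import Path

import scapreli as sr

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dataset = sr.read_landmark_csv(RESULTS / "landmarks.csv")
    report = sr.validate_dataset(dataset)
    if not report.usable:
        raise SystemExit(report.summary())
    coords, angles = sr.compute_coordinates_and_orientations(dataset)
    coords.to_csv(RESULTS / "coordinates.csv", index=False)
    angles.to_csv(RESULTS / "orientations.csv", index=False)
    print(f"{len(coords)} coordinate rows, {len(angles)} orientation rows")
    for col, label in (("e1_deg", "e1 retraction/protraction"),
                       ("e2_deg", "e2 lateral/medial rotation"),
                       ("e3_deg", "e3 internal/external rotation")):
        s = angles[col]
        print(f"{label}: mean {s.mean():6.2f} deg, sd {s.std():.2f} deg, "
              f"range [{s.min():.2f}, {s.max():.2f}]")


if __name__ == "__main__":
    main()
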