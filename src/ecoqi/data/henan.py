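"""Published worked-example values from a Henan Province case study.

Two small tables from a provincial eco-environment assessment serve as
in-repo worked examples:

* ``HENAN_ANNUAL_INDEX`` — province-wide annual index values of the EI, EQI
  and composite (S_CEQI) models for four assessment years, used to
  exercise the deviation statistics.
* ``WHEAT_POINT_SERIES`` — four winter-wheat sample points observed on four
  2018 dates (jointing, heading, grain-filling, maturity stages), each with
  the raw single-phase index value before normalization ("original"), the
  static per-scene normalized value ("static", the RSEI convention) and the
  full-sequence normalized value ("full_sequence").  These anchor the
  dimensionless-method reconstructions and the order-inversion
  demonstration: p1 on 2018-05-10 exceeds p4 on 2018-03-23 in the raw data
  and under the full-sequence map, but not under the per-scene static maps.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["HENAN_ANNUAL_INDEX", "WHEAT_POINT_SERIES"]

#: Annual province-wide index values per model (unit scale), 2005-2019.
HENAN_ANNUAL_INDEX = pd.DataFrame(
    {
        "year": [2005, 2010, 2015, 2019],
        "ei": [0.479, 0.486, 0.489, 0.473],
        "eqi": [0.366, 0.364, 0.365, 0.411],
        "sceqi": [0.500, 0.500, 0.496, 0.491],
    }
)

#: Winter-wheat sample points: raw value and both dimensionless results.
WHEAT_POINT_SERIES = pd.DataFrame(
    [
        # point, date, original, static (per-scene), full_sequence
        ("p1", "2018-03-23", 0.565, 0.754, 0.818),
        ("p1", "2018-04-08", 0.764, 0.930, 0.953),
        ("p1", "2018-05-10", 0.656, 0.831, 0.879),
        ("p1", "2018-06-11", 0.220, 0.555, 0.583),
        ("p2", "2018-03-23", 0.636, 0.840, 0.866),
        ("p2", "2018-04-08", 0.771, 0.938, 0.958),
        ("p2", "2018-05-10", 0.673, 0.847, 0.891),
        ("p2", "2018-06-11", 0.185, 0.527, 0.560),
        ("p3", "2018-03-23", 0.673, 0.886, 0.891),
        ("p3", "2018-04-08", 0.774, 0.941, 0.960),
        ("p3", "2018-05-10", 0.596, 0.774, 0.839),
        ("p3", "2018-06-11", 0.202, 0.540, 0.571),
        ("p4", "2018-03-23", 0.629, 0.832, 0.861),
        ("p4", "2018-04-08", 0.759, 0.925, 0.949),
        ("p4", "2018-05-10", 0.666, 0.841, 0.886),
        ("p4", "2018-06-11", 0.222, 0.556, 0.585),
    ],
    columns=["point", "date", "original", "static", "full_sequence"],
)
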