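"""Build the Soil Degradation Proxy from raw indicator values.

Fits directional empirical-CDF rescalers on a small hand-made survey
and aggregates the four soil health indicators into the SDP.
"""

import pandas as pd

from sdproxy import build_sdp_table

table = pd.DataFrame(
    {
        "erosion_rate": [1, 2, 2, 5, 3, 10],  # t/ha/yr
        "ec": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],  # dS/m
        "ph": [5.0, 6.5, 7.0, 8.0, 6.0, 6.5],
        "soc": [30, 20, 10, 5, 25, 15],  # g/kg
    }
)

out = build_sdp_table(table)
print(out[["erosion_rate", "ec", "ph", "soc", "shi_er", "shi_ec", "shi_ph", "shi_soc", "sdp"]])
print()
print(
    "Each SHI is the indicator's ECDF value oriented so higher = worse\n"
    "(pH rises as it departs from 6.5 on either side); the SDP is their\n"
    "equal-weight mean, 0 = healthiest to 1 = most degraded in this sample."
)
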