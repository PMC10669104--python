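"""Reference benchmark tables bundled with the package.

Two small per-track tables from a published hand-held smartphone CASA
evaluation of boar semen are shipped as validation inputs: one of tracking
scores (appear/disappear frames, frames tracked Ft, frames present Fw,
tracking rate Rt) and one of motility kinematics with WHO-style grades.
They exercise the tracking-rate and ratio arithmetic against independently
printed values.
"""

from __future__ import annotations

import io as _io

import pandas as pd

_TRACKING_CSV = """\
id,appear,disappear,ft,fw,rt
1,1,72,72,72,100
2,1,55,55,90,61.11
3,1,44,45,45,100
5,1,90,90,90,100
9,5,31,27,42,64.29
15,6,90,85,85,100
17,8,52,45,83,54.22
24,9,29,11,62,17.74
25,12,90,79,79,100
27,13,90,78,78,100
43,21,90,70,70,100
45,23,66,44,68,64.70
56,25,61,37,37,100
63,25,90,66,66,100
74,28,90,63,63,100
87,28,90,63,63,100
89,54,90,36,36,100
"""

_MOTILITY_CSV = """\
id,vcl,vsl,vap,lin,str,wob,grade
1,13.63,6.02,8.63,44.17,69.76,63.32,C
3,27.42,14.65,22.57,53.13,64.91,82.31,B
5,19.44,10.51,13.92,54.06,75.50,71.60,C
15,11.95,6.27,8.17,52.47,68.37,76.74,C
25,15.35,4.99,7.14,32.51,69.89,46.51,C
27,10.19,3.63,5.94,35.62,58.29,61.11,C
43,5.86,4.62,5.35,78.83,94.37,86.36,D
56,20.65,12.46,17.79,60.34,70.04,86.15,C
63,13.11,8.05,9.93,61.40,81.07,75.74,C
89,25.39,10.66,16.28,39.39,65.48,64.12,B
"""

#: Motility-table rows whose printed LIN/STR/WOB are internally consistent
#: with the VSL/VCL/VAP definitions at 2-decimal rounding; the remaining
#: rows carry transcription slips (swapped or off ratios) in the source.
MOTILITY_SELF_CONSISTENT_IDS = (1, 5, 25, 56, 63)

#: Tracking-table row whose printed Rt was truncated rather than rounded
#: (100·44/68 = 64.7059 printed as 64.70).
TRACKING_TRUNCATED_IDS = (45,)


def load_tracking_benchmark() -> pd.DataFrame:
    """17 tracked cells: appear/disappear frame, Ft, Fw and printed Rt (%)."""
    return pd.read_csv(_io.StringIO(_TRACKING_CSV))


def load_motility_benchmark() -> pd.DataFrame:
    """10 cells: VCL/VSL/VAP (µm/s), LIN/STR/WOB (%) and grade A–D."""
    return pd.read_csv(_io.StringIO(_MOTILITY_CSV))
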