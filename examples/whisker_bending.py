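"""Bend one whisker against a wall and read out its afferent signal.

Places a wall in reach of the longest left whisker, resolves the
quasistatic bending and prints the perturbed curvature, the shaft deviation
at the 5 mm measurement point and the saturating contact signal.
"""

import numpy as np

from vibrisim import Params
from vibrisim.params import ObstacleSpec
from vibrisim.plane import HeadPose, build_morphology, resolve_bending

params = Params()
morphs = build_morphology(params)
pose = HeadPose(fovea=np.zeros(2), neck=np.array([-50.0, 0.0]))
whisker = morphs[0]            # most caudal left whisker, 44 mm

for wall_y in (60.0, 45.0, 38.0, 33.0):
    wall = ObstacleSpec(cx_mm=0.0, cy_mm=wall_y, width_mm=300.0,
                        height_mm=20.0)
    res = resolve_bending(whisker, 100.0, pose, [wall], params)
    print(f"wall face at y = {wall_y - 10.0:5.1f} mm: "
          f"curvature {res.perturbed_curvature:+.4f} 1/mm, "
          f"deviation {res.deviation:5.2f} mm, "
          f"contact signal {res.contact_signal:.3f}")

# The closer the wall face, the more the shaft must bend caudally: the
# deviation of the near-base measurement point grows and the contact signal
# saturates toward 1.
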