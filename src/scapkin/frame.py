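"""Global laboratory frame conventions.

Every module in the package uses the same right-handed laboratory frame:

- ``UP`` (+z) opposes gravity; ``GRAVITY_DIR`` (-z) is the direction a
  plumb line points.
- ``FORWARD`` (+x) is the direction the seated subject faces.
- ``LEFT`` (+y) completes the right-handed triad (x cross y = z).

Marker coordinates are millimetres, angles are degrees unless a function
explicitly says otherwise.
"""

import numpy as np

UP = np.array([0.0, 0.0, 1.0])
GRAVITY_DIR = -UP
FORWARD = np.array([1.0, 0.0, 0.0])
LEFT = np.array([0.0, 1.0, 0.0])
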