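"""Basic parameter sweep: z = x * y over a Cartesian product.

The environment evokes the model once per parameter point, collects the
returned values, and stores every run's result into one HDF5 file.
"""

import tempfile, os

from trajkit import Environment, cartesian_product
from trajkit.models import multiply

tmp = tempfile.mkdtemp()
env = Environment(trajectory="multiply",
                  filename=os.path.join(tmp, "multiply.h5"))
traj = env.traj

traj.add_parameter("x", 1.0, comment="I am the first dimension!")
traj.add_parameter("y", 1.0, comment="I am the second dimension!")

# all 4 x 3 = 12 combinations; the first-listed parameter cycles fastest
traj.explore(cartesian_product({"x": [1.0, 2.0, 3.0, 4.0],
                                "y": [6.0, 7.0, 8.0]}))

outcomes = env.run(multiply)
env.close()

# each tuple is (run index, returned z); run 1 is the point (2.0, 6.0)
print(outcomes)
# -> [(0, 6.0), (1, 12.0), ..., (11, 32.0)]
print("results stored in", env.filename)
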