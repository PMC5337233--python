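"""The published exemplar conversion matrices, frozen for bit-exact checks."""

import numpy as np

# isotopomer -> cumomer matrices, keyed (n, m)
IC_TABLE = {
    (0, 0): [[1]],
    (1, 0): [[1]],
    (2, 0): [[1]],
    (0, 1): [[1]],
    (1, 1): [[1, 0], [0, 1], [1, 1]],
    (2, 1): [
        [1, 0, 0, 0],
        [0, 1, 0, 0],
        [1, 1, 0, 0],
        [0, 0, 1, 0],
        [0, 0, 0, 1],
        [0, 0, 1, 1],
        [1, 0, 1, 0],
        [0, 1, 0, 1],
        [1, 1, 1, 1],
    ],
    (0, 2): [[1]],
    (1, 2): [[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]],
    (2, 2): [
        [1, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 1, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 1, 0, 0, 0, 0, 0, 0],
        [1, 1, 1, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 1, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 1, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 1, 0, 0, 0],
        [0, 0, 0, 1, 1, 1, 0, 0, 0],
        [0, 0, 0, 0, 0, 0, 1, 0, 0],
        [0, 0, 0, 0, 0, 0, 0, 1, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 1],
        [0, 0, 0, 0, 0, 0, 1, 1, 1],
        [1, 0, 0, 1, 0, 0, 1, 0, 0],
        [0, 1, 0, 0, 1, 0, 0, 1, 0],
        [0, 0, 1, 0, 0, 1, 0, 0, 1],
        [1, 1, 1, 1, 1, 1, 1, 1, 1],
    ],
}

# isotopomer -> mass matrices, keyed (n, m)
IM_TABLE = {
    (0, 0): [[1]],
    (1, 0): [[1]],
    (2, 0): [[1]],
    (0, 1): [[1]],
    (1, 1): [[1, 0], [0, 1]],
    (2, 1): [[1, 0, 0, 0], [0, 1, 1, 0], [0, 0, 0, 1]],
    (0, 2): [[1]],
    (1, 2): [[1, 0, 0], [0, 1, 0], [0, 0, 1]],
    (2, 2): [
        [1, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 1, 0, 1, 0, 0, 0, 0, 0],
        [0, 0, 1, 0, 1, 0, 1, 0, 0],
        [0, 0, 0, 0, 0, 1, 0, 1, 0],
        [0, 0, 0, 0, 0, 0, 0, 0, 1],
    ],
}

IC_TABLE = {k: np.array(v) for k, v in IC_TABLE.items()}
IM_TABLE = {k: np.array(v) for k, v in IM_TABLE.items()}
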