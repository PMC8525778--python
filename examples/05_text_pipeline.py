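"""From raw text to a model trajectory via a word-embedding table.

Uses a tiny inline word2vec-format table; a real analysis would point
`read_word_vectors` at a pretrained 100-dimensional table instead.
"""

import tempfile
from pathlib import Path

import numpy as np

from reservoir_events import (
    IntegratorParams,
    read_word_vectors,
    run_linear_integrator,
    text_to_sequence,
)

W2V = """7 4
cat 0.9 0.1 0.0 0.2
dog 0.8 0.2 0.1 0.1
sat 0.0 0.9 0.3 0.0
mat 0.1 0.8 0.2 0.3
ran 0.2 0.0 0.9 0.1
fast 0.0 0.1 0.8 0.4
home 0.3 0.2 0.1 0.9
"""

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "vecs.txt"
    path.write_text(W2V)
    table = read_word_vectors(path)

text = "The cat sat on the mat. Then the dog ran fast to its home."
seq = text_to_sequence(text, table)
print("retained tokens:", seq.tokens)
print("dropped (out of vocabulary):", seq.meta["oov"])
print("stream shape:", seq.matrix.shape)

traj = run_linear_integrator(IntegratorParams(alpha=0.2, D=4), seq)
print("final integrator state:", np.round(traj.states[-1], 3))
print()
print("Each retained word is one time step; the integrator state is a")
print("leaky running summary of the word-embedding stream.")
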