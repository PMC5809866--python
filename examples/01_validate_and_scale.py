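"""Read, validate and scale a count table.

Builds a tiny transcript-by-sample table, writes it in the tab-separated
dialect the package reads, validates it on the way back in, applies the
intra-sample scaling (each sample divided by its own maximum count) and
the zero-count pre-filter used before comparative analysis.
"""

import tempfile
from pathlib import Path

import pandas as pd

from plawcorrect import (
    CountMatrix,
    filter_nonzero,
    intra_sample_scale,
    read_counts,
    write_counts,
)

df = pd.DataFrame(
    {"liver_1": [500, 40, 8, 0], "liver_2": [460, 44, 0, 3]},
    index=["mir-21", "mir-148a", "mir-375", "mir-9"],
)
path = Path(tempfile.mkdtemp()) / "counts.tsv"
write_counts(CountMatrix(df), path)

m = read_counts(path)
print(f"read {m.shape[0]} transcripts x {m.shape[1]} samples, "
      f"library sizes {m.library_sizes().tolist()}")

scaled = intra_sample_scale(m)
print("scaled liver_1:", scaled.data["liver_1"].tolist())
# the most abundant transcript maps to exactly 1; zeros stay zero,
# so every sample shares the (0, 1] amplitude convention of the
# rank-frequency machinery.

kept = filter_nonzero(m, [["liver_1"], ["liver_2"]])
print("retained after zero filter:", kept.transcript_ids)
# mir-375 and mir-9 each vanish in one sample: their fold changes would
# be infinite, so the pre-filter drops them before any comparison.
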