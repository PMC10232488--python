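"""Generate a synthetic tile dataset and apply the 60-20-20 hold-out split.

The generator writes a class-per-folder PNG tree with the same layout as
the public colorectal tile collections; the split is stratified per class
with a seeded shuffle, so counts are exact and membership reproducible.
"""

import tempfile
from pathlib import Path

import histotile as ht

work = Path(tempfile.mkdtemp())
spec = ht.SyntheticSpec(n_classes=8, tiles_per_class=50, tile_size=(64, 64),
                        noise_sd=8.0, seed=1)
manifest = ht.generate_dataset(spec, work / "tiles")
manifest = ht.stratified_split(manifest, ht.SplitRatios(), seed=1)

print(f"{len(manifest)} tiles in {manifest.n_classes} classes under {work}")
print(f"{'class':<10}{'train':>7}{'val':>6}{'test':>6}")
for cls, row in manifest.counts().items():
    print(f"{cls:<10}{row['train']:>7}{row['val']:>6}{row['test']:>6}")
totals = manifest.split_totals()
print(f"{'total':<10}{totals['train']:>7}{totals['val']:>6}{totals['test']:>6}")
# Each class of 50 tiles splits 30/10/10: val and test round 0.2*n, train
# absorbs the remainder, so no tile is dropped or duplicated.
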