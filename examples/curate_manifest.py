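"""Curate a radiograph dataset manifest: filter, split, summarize.

Generates a synthetic manifest with the reference label imbalance, applies
the exclusion rules (PA view only, adults only, de-duplication), performs
a patient-disjoint 9:1 train/tune split, and prints the distribution
summary of the training side.
"""

from dataclasses import replace

from cxrctr import filter_manifest, split_manifest, summarize_manifest
from cxrctr.annot_io import DatasetManifest
from cxrctr.synthetic import generate_manifest

manifest = generate_manifest(n_images=2000, seed=3)

# contaminate with records the exclusion rules must remove
records = list(manifest.records)
records[0] = replace(records[0], view="lateral")
records[1] = replace(records[1], age=16.0)
records[2] = replace(records[2], view=None)
manifest = DatasetManifest(tuple(records), manifest.category_list)

kept, log = filter_manifest(manifest)
print(f"filtered {len(manifest)} -> {len(kept)} records")
for image_id, reason in log:
    print(f"  excluded {image_id}: {reason}")

train, tune = split_manifest(kept, tune_fraction=0.1, seed=11)
overlap = train.patient_ids & tune.patient_ids
print(f"\nsplit: {len(train)} train / {len(tune)} tune records "
      f"({len(train.patient_ids)}/{len(tune.patient_ids)} patients, "
      f"{len(overlap)} shared)")

print("\ntraining-side distribution:")
print(summarize_manifest(train).format())
print("\nShares are percentages of all boxes; a patient never appears on")
print("both sides of the split, so tuning scores are not inflated by")
print("per-patient correlation.")
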