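"""Generate a synthetic pediatric cohort and write RR files plus a manifest.

Each subject gets an AHI drawn from a four-group severity mixture, an
age, a subject-specific respiratory frequency, and an overnight RR tachogram
whose apnea-band (0.028-0.074 Hz) modulation grows with AHI.
"""

from collections import Counter

from hrvbispec import synthetic as syn

cohort = syn.generate_cohort(n=8, seed=42, ahi_mix=(0.25, 0.25, 0.25, 0.25))
manifest = syn.write_cohort(cohort, "scratch/example_cohort")

print(manifest[["subject_id", "ahi", "age", "severity"]].to_string(index=False))
print("\nseverity counts:", dict(Counter(manifest["severity"])))
print("RR files + manifest.csv written to scratch/example_cohort/")
# Each severity label follows the pediatric AHI partition (1/5/10 events/h);
# the RR files are plain text, one interval in seconds per line.
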