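"""Generate a synthetic infant-weight cohort with known faltering episodes.

Builds 10 subjects measured in triplicate every other day from day 9 to 365,
with replicate noise at the technical-error-of-measurement scale (5 g) and
cosine-shaped faltering episodes carved into each growth curve, then prints
the injected ground truth.
"""

import falterscan as fs

subjects = fs.simulate_cohort(10, seed=42)
measurements, truth = fs.cohort_to_frames(subjects)

print(f"{len(subjects)} subjects, {len(measurements)} scheduled visits")
print(f"{len(truth)} injected episodes "
      f"({len(truth) / len(subjects):.2f} per subject)\n")
print(truth.head(8).to_string(index=False))
print(
    "\nEach row is one injected episode: the day weight loss began, how many"
    "\ndays the loss lasted (dip), how many grams were lost at most (depth),"
    "\nand how many days the regain took (rebound)."
)
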