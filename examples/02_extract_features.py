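"""Extract radiomic features for one phantom subject.

Shows the 5912-dimensional feature space layout (shape once from the mask;
intensity/histogram per image version; five texture families per image
version and quantization level) and a few named values.
"""

from gliorad import (
    ExtractionConfig,
    PhantomConfig,
    enumerate_feature_space,
    extract_subject,
    generate_cohort,
    preprocess_subject,
)

subject = generate_cohort(PhantomConfig(n_grade3=1, n_grade4=1, grid_shape=(48,) * 3, seed=3))[1]
subject = preprocess_subject(subject)  # isotropic + whole-brain Z-score

config = ExtractionConfig()
descriptors = config.descriptors()
row = extract_subject(subject, config)
print(f"{len(row)} features extracted for {subject.subject_id} (grade {subject.grade})")

for name in (
    "mask|orig|none|shape|volume",
    "mask|orig|none|shape|sphericity",
    "CE-T1|orig|none|intensity|median",
    "T2|LLL|none|intensity|root_mean_square",
    "CE-T1|HLL|7bit|GLSZM|gray_level_variance",
    "CE-T1|LHL|8bit|GLRLM|run_length_variance",
):
    i = [str(d) for d in descriptors].index(name)
    print(f"  {name:45s} = {row[i]:.4f}")
# volume is in mm^3; intensity statistics are in whole-brain Z units; the
# texture features are dimensionless summaries of the quantized tumor ROI.
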