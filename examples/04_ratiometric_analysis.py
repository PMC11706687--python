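"""Full ratiometric study: zone means and Welch's t-tests per group.

Simulates the two-line × two-treatment design (wildtype Col-0 responds to
brassinolide with a multiplicative drop of the 458/405 ratio — apoplastic
acidification — while the receptor mutant bri1-301 does not), quantifies
per-zone mean ratios over ground-truth masks, and runs the standard group
contrasts.
"""

from phroot.image_io import SampleRecord
from phroot.ratiometrics import (
    compute_ratio_image,
    comparisons_frame,
    group_statistics,
    zone_mean_ratio,
)
from phroot.synthetic import SyntheticConfig, generate_dataset

groups = [("Col-0", "mock"), ("Col-0", "BL"), ("bri1-301", "mock"), ("bri1-301", "BL")]
config = SyntheticConfig(image_size=96, seed=21)  # 5% multiplicative noise
samples, metadata = generate_dataset(config, 10, groups)

records, measures = [], []
for sample, row in zip(samples, metadata.itertuples()):
    records.append(SampleRecord(row.sample_id, row.line, row.treatment, row.file))
    ratio = compute_ratio_image(sample.image)
    for zone in ("EEZ", "LEZ", "MZ"):
        measures.append(zone_mean_ratio(ratio, sample.mask, zone, row.sample_id))

frame = comparisons_frame(group_statistics(measures, records))
cols = ["zone", "group_a", "group_b", "t_statistic", "df", "p_value"]
print(frame[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
# Expected pattern: Col-0 mock-vs-BL is significant in every zone (the
# generator's 20% ratio shift dwarfs the noise), bri1-301 mock-vs-BL is not,
# and BL-treated Col-0 differs from BL-treated bri1-301.
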