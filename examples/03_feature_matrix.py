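"""Build the 6,580-column band-power feature matrix.

Each channel contributes 470 features: 41 base statistics computed on the
broadband signal and on each of six frequency bands (delta through gamma),
plus 183 cross-band power ratios (absolute, relative, pairwise and
engagement-style composites).
"""

from neuroads import (
    PreprocessConfig,
    SimulationConfig,
    build_feature_matrix,
    clean_epochs,
    generate_dataset,
)
from neuroads.features import FeatureRegistry, default_registry
from neuroads.synthgen import DEFAULT_ADS
from neuroads.types import AdSpec

ads = tuple(AdSpec(a.ad_id, a.topic, a.style, 10.0) for a in DEFAULT_ADS)
config = SimulationConfig(n_subjects=2, ads=ads, seed=3)
dataset = generate_dataset(config)

epochs = []
for rec in dataset.recordings:
    epochs.extend(clean_epochs(rec, config.ads, dataset.ratings,
                               PreprocessConfig(ica_enabled=False)))

registry = default_registry()
fm = build_feature_matrix(epochs, registry)
print(f"feature matrix: {fm.shape[0]} epochs x {fm.shape[1]} features "
      f"(= 14 channels x {registry.per_channel_count})")

col = "AF3__crossband__cmp_beta_over_alpha_abs"
ch, signal, feat = FeatureRegistry.parse_column(col)
print(f"example column {col!r}: channel={ch}, signal={signal}, feature={feat}")
print(fm[col].describe().round(3).to_string())
# This column is the frontal beta/alpha engagement index; it is one of the
# ratio features guaranteed to be present in the registry.
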