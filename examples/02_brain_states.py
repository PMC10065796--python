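"""Cluster seizure evolution into brain states.

Quantized multilayer-centrality matrices of one patient's seizures are
decomposed with the SVD; the top three right singular vectors per
high-frequency band (Hampel-despiked) describe how network centrality
evolves through each seizure.  K-means over every 4-of-6 feature
combination and k = 2..8, selected by silhouette, yields per-window brain
states and the state-transition structure.

Runtime: about 20 seconds.
"""

from ictalnet.ezdetect import assemble_features, quantize
from ictalnet.multilayer import mlevc_from_series
from ictalnet.pipeline import HF_BANDS, detection_inputs, seizure_layers  # noqa: F401
from ictalnet.states import clean_right_vectors, select_state_model, transitions
from ictalnet.synthetic import SimConfig, simulate_cohort

patient = simulate_cohort(
    n_patients=1, seizures_per_patient=2,
    template=SimConfig(seizure_s=20.0), seed=1,
)
series_by_key, _ = detection_inputs(patient)

c, d = 3.0, 0.4  # one illustrative cell of the consensus grid
quantized, keys = [], []
for (sz, band), series in series_by_key.items():
    m = mlevc_from_series(series, c, seizure_id=sz, band=band)
    quantized.append(quantize(m, d))
    keys.append((sz, band))

space = assemble_features(quantized, keys)
feats = clean_right_vectors(space)
model = select_state_model(feats, seed=0)
seqs, counts = transitions(model, feats.window_seizure)

print(f"states k = {model.k}   silhouette = {model.silhouette:.3f}"
      f"   features = v{list(model.chosen_features)}")
if model.weak:
    print("note: silhouette < 0.25, clustering structure is weak")
for sz, seq in seqs.items():
    print(f"  {sz}: state sequence {seq}")
print("transition counts:")
print(counts)
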