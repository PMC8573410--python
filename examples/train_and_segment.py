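"""Train a small segmenter on phantoms and segment held-out normal/malformed cases.

Desk-scale version of the full pipeline: a narrow (base-width-4) U-Net is
trained on normal phantoms with corrected-mask targets, then applied to a
held-out normal and a malformed phantom.  The contrast of the two Dice
scores is the malformation signal.  Takes a few minutes on one CPU.
"""

from dataclasses import replace

from chiasmseg import (
    AugmentParams,
    InferenceParams,
    NetConfig,
    PhantomParams,
    TrainConfig,
    correct_mask,
    corrupt_to_initial,
    extract_cnn_mask,
    make_phantom,
    predict_probability,
    slice_restricted_dsc,
    train,
)
from chiasmseg.phantom import malformed_preset, sample_seed

base = PhantomParams()
pairs = []
for i in range(12):
    s = make_phantom(replace(base, seed=sample_seed(0, i)))
    initial = corrupt_to_initial(s, corruption_seed=s.seed + 1)
    pairs.append((s.volume.data, correct_mask(s.volume, initial).data))

net, history = train(
    pairs,
    NetConfig(base_width=4),
    TrainConfig(batch_size=2, max_epochs=10, learning_rate=0.02, seed=0),
    AugmentParams(crop_size=(64, 64, 64), max_rotation=0, max_translation=0, affine=False),
)
print("training loss per epoch:", " ".join(f"{l:.3f}" for l in history["train_loss"]))

# tau = 0.75 from the studied threshold range; the fully-trained protocol
# uses tau = 1.0, which needs a saturated softmax (longer training)
for name, params in (
    ("normal   ", replace(base, seed=sample_seed(900, 0))),
    ("malformed", malformed_preset(replace(base, seed=sample_seed(900, 1)))),
):
    s = make_phantom(params)
    prob = predict_probability(net, s.volume)
    mask = extract_cnn_mask(prob, InferenceParams(threshold=0.75))
    d = slice_restricted_dsc(mask, s.manual_mask)
    print(f"{name} phantom: slice-restricted DSC = {d:.3f}")

print("A segmenter trained on normal anatomy only reproduces normal chiasms")
print("well but degrades on malformed ones - that gap is the detection signal.")
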