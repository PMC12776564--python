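"""Canonical problem sizes and the desk-scale training configuration.

The simulation conditions (sample counts, split ratio, phantom and
protocol parameters) follow the study design; the training configuration
is the package's single-CPU working point, chosen once: a depth-3,
base-8-channel network (the 32x32 grid leaves little to gain from a
deeper pyramid) trained with Adam under a cosine learning-rate schedule.
The methods note discusses these choices.
"""

N_TRAINVAL = 1000
N_TEST = 200
SPLIT_RATIO = 0.9

DESK_TRAINING = dict(
    base_channels=8,
    depth=3,
    learning_rate=3e-3,
    batch_size=16,
    epochs=40,
    patience=40,
)
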