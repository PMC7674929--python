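"""Featurize a 30 s EEG epoch into the time-frequency matrix the classifier
consumes.

A 1 s Hamming window with 50% overlap and no padding gives exactly 59 frames
for a 30 s epoch at any supported rate, with 1 Hz frequency resolution.  At
128 Hz the full one-sided spectrum is kept (65 bins); at 256/512 Hz bins up
to 90 Hz are kept minus the 55-64 Hz power-line band (81 bins).
"""

import numpy as np

from preictal import freq_mask, stft_features

rng = np.random.default_rng(0)

for fs in (128, 256, 512):
    epoch = rng.standard_normal((1, 30 * fs))  # one channel, 30 s
    tf = stft_features(epoch, fs)
    bins = freq_mask(fs)
    print(f"fs = {fs:>3} Hz: matrix {tf.shape[1]} frames x {tf.shape[2]} bins, "
          f"bins {bins[0]}-{bins[-1]} Hz"
          + ("" if fs == 128 else " (55-64 Hz excluded)"))

# A 20 Hz tone lands in its 1 Hz bin:
fs = 256
t = np.arange(30 * fs) / fs
tone = np.sin(2 * np.pi * 20 * t)[None, :]
tf = stft_features(tone, fs)
peak = freq_mask(fs)[np.argmax(tf.mean(axis=1))]
print(f"20 Hz tone peaks in the {peak} Hz bin")
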