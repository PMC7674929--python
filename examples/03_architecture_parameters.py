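"""Build the CNN declaratively and account for every trainable parameter.

The model has three convolution blocks (64 maps: an n x 5 x 5 kernel with
stride 2, then two 3 x 3 kernels with stride 1, each with batch norm, ReLU
and 2 x 2 max pooling, all unpadded), a 256-unit FC layer with dropout 0.5,
and one sigmoid output.  Because only the first convolution sees the n EEG
channels, shrinking the montage shrinks the model: the 4-, 8- and 16-channel
models need only 60.9%, 63.1% and 67.4% of the 76-channel model's
parameters, and the 128 Hz model needs 86.2% of the 256-512 Hz model at 40
channels.
"""

from preictal import build_architecture, count_parameters, spatial_trace

spec76 = build_architecture(n_channels=76, fs_out=256)
print("spatial trace (59 x 81 input):", spatial_trace(spec76))
p76 = count_parameters(spec76)
print(f"76-channel model: {p76:,} trainable parameters")

for n in (4, 8, 16):
    p = count_parameters(build_architecture(n, 256))
    print(f"{n:>2}-channel model: {p:,} parameters = {100 * p / p76:.1f}% of all-channel")

p40_128 = count_parameters(build_architecture(40, 128))
p40_256 = count_parameters(build_architecture(40, 256))
print(f"40 channels, 128 vs 256 Hz: {p40_128:,} / {p40_256:,} "
      f"= {100 * p40_128 / p40_256:.1f}%")
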