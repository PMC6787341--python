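# Demo pipeline configuration: simulate an RPPM slide and a behavioral
# table, quantify, and run the factorial statistics.
#   rmtbi-markers run --config examples/pipeline.yaml --seed 1 --out out/
stages: [rppm, dwi, behavior]
seed: 1
n_samples: 16
n_dilutions: 8
snr_min: 2.0
net_min: 10.0
fdr_q: 0.01
band: [0.25, 0.75]
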