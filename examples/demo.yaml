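# Full synthetic demo run: simulate the default study design and execute
# every analysis stage. See docs/methods.md for what the defaults emulate.
out_dir: demo_out
seed: 1
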