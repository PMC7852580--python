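from hypothesis import settings

# deterministic property tests: same example sequence on every run
settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")
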