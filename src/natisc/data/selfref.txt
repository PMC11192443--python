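i think
i believe
i guess
i suppose
i assume
i imagine
i feel like
i felt like
in my opinion
to me
i thought
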