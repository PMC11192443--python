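it appears to be
appears to be
it appears
it seems like
seems like
it seems
seems to be
it looks like
looks like
it might be
might be
maybe
possibly
probably
perhaps
i am not sure
i'm not sure
not sure
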