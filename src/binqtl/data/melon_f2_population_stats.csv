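population,n_individuals,total_recombination_events,covered_mb,n_bins
WAP,200,5138,306.5,954
MAP,200,5839,309.6,1027
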