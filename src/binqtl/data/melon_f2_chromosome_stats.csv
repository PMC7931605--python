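population,chrom,n_bins,length_cm
WAP,chr1,85,93.86
WAP,chr2,74,70.57
WAP,chr3,90,63.03
WAP,chr4,94,97.01
WAP,chr5,64,85.78
WAP,chr6,90,88.61
WAP,chr7,79,88.95
WAP,chr8,91,70.30
WAP,chr9,65,67.02
WAP,chr10,62,49.89
WAP,chr11,99,73.76
WAP,chr12,61,55.65
MAP,chr1,86,74.92
MAP,chr2,70,73.14
MAP,chr3,98,78.66
MAP,chr4,109,68.04
MAP,chr5,79,67.94
MAP,chr6,108,84.08
MAP,chr7,64,66.44
MAP,chr8,92,78.61
MAP,chr9,74,61.25
MAP,chr10,73,62.42
MAP,chr11,96,78.73
MAP,chr12,78,80.26
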