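patient_id,stated_reference_phase,site,mean_gtv_cm3
1,,right middle lobe,90
2,,left lower lobe,403
3,,right paratracheal,27
4,,right upper lobe,86
5,,right lower lobe,2
6,,right lower lobe,2
7,,right upper lobe,7
8,,right upper lobe,10
9,6,left lower lobe,2
10,,left lower lobe,68
11,,left upper lobe,37
12,,right middle lobe,66
13,,right upper lobe,6
14,,right lower lobe,10
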