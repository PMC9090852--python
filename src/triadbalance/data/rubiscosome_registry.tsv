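gene_name	gene_id	subgenome_override
Bsd2	TraesCS7A02G341000
Bsd2	TraesCS7B02G242200
Bsd2	TraesCS7D02G338600
CA1Pase	TraesCS4A02G184100
CA1Pase	TraesCS4B02G134600
CA1Pase	TraesCS4D02G129300
Cpn20	TraesCS6A02G340300
Cpn20	TraesCS5A02G212500
Cpn20	TraesCS7A02G161000
Cpn20	TraesCS2A02G146000
Cpn20	TraesCS6B02G371500
Cpn20	TraesCS5B02G211200
Cpn20	TraesCS7B02G066000
Cpn20	TraesCS2B02G171400
Cpn20	TraesCS6D02G320800
Cpn20	TraesCS5D02G219500
Cpn20	TraesCS7D02G162300
Cpn20	TraesCS2D02G150600
Cpn60	TraesCS4A02G315500
Cpn60	TraesCS5A02G366800
Cpn60	TraesCS5B02G563900
Cpn60	TraesCS5B02G368900
Cpn60	TraesCS5D02G550700
Cpn60	TraesCS5D02G376000
Raf1	TraesCS1A02G142000
Raf1	TraesCS1B02G159700
Raf1	TraesCS1D02G141100
Raf2	TraesCS5A02G545700
Raf2	TraesCS4B02G379500
Raf2	TraesCSU02G129700	D
RbcS	TraesCS2A02G066700
RbcS	TraesCS2A02G066800
RbcS	TraesCS2A02G066900
RbcS	TraesCS2A02G067000
RbcS	TraesCS2A02G067100
RbcS	TraesCS2A02G067200
RbcS	TraesCS2A02G067300
RbcS	TraesCS5A02G165400
RbcS	TraesCS5A02G165700
RbcS	TraesCS2B02G079100
RbcS	TraesCS2B02G079200
RbcS	TraesCS2B02G079300
RbcS	TraesCS2B02G079400
RbcS	TraesCS2B02G079500
RbcS	TraesCS2B02G078900
RbcS	TraesCS5B02G162600
RbcS	TraesCS5B02G162800
RbcS	TraesCS2D02G065100
RbcS	TraesCS2D02G065200
RbcS	TraesCS2D02G065300
RbcS	TraesCS2D02G065400
RbcS	TraesCS2D02G065500
RbcS	TraesCS2D02G065600
RbcS	TraesCS5D02G169600
RbcS	TraesCS5D02G169900
RbcX	TraesCS2A02G198700
RbcX	TraesCS5A02G459200
RbcX	TraesCS2B02G226100
RbcX	TraesCS5B02G468800
RbcX	TraesCS2D02G206500
RbcX	TraesCS5D02G470300
Rca1	TraesCS4A02G177600
Rca1	TraesCS4B02G140200
Rca1	TraesCS4D02G134900
Rca2	TraesCS4A02G177500
Rca2	TraesCS4B02G140300
Rca2	TraesCS4D02G135000
XuBPase	TraesCS7A02G335600
XuBPase	TraesCS7B02G247200
XuBPase	TraesCS7D02G343300
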