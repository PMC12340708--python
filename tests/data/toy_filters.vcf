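##fileformat=VCFv4.2
##source=rohpipe-test-fixture
##contig=<ID=chr1,length=2000000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=GL,Number=G,Type=Float,Description="log10 genotype likelihoods">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	s01	s02	s03	s04	s05	s06	s07	s08	s09	s10	s11	s12	s13	s14	s15	s16	s17	s18	s19	s20
chr1	1000	.	A	T,G	.	PASS	DP=400	GT:AD:DP:GQ:GL	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20	./.:20,0,0:20:50:0,-5,-20,-5,-20,-20
chr1	2000	.	A	G	.	PASS	DP=320	GT:AD:DP:GQ:GL	./.:0,0:0:0:0,0,0	./.:0,0:0:0:0,0,0	./.:0,0:0:0:0,0,0	./.:0,0:0:0:0,0,0	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:0,20:20:50:-20,-5,0	./.:0,20:20:50:-20,-5,0
chr1	3000	.	A	G	.	PASS	DP=100	GT:AD:DP:GQ:GL	./.:5,0:5:25:0,-2.5,-10	./.:5,0:5:25:0,-2.5,-10	./.:5,0:5:25:0,-2.5,-10	./.:5,0:5:25:0,-2.5,-10	./.:5,0:5:25:0,-2.5,-10	./.:5,0:5:25:0,-2.5,-10	./.:5,0:5:25:0,-2.5,-10	./.:5,0:5:25:0,-2.5,-10	./.:5,0:5:25:0,-2.5,-10	./.:5,0:5:25:0,-2.5,-10	./.:5,0:5:25:0,-2.5,-10	./.:5,0:5:25:0,-2.5,-10	./.:3,2:5:25:-2.5,0,-2.5	./.:3,2:5:25:-2.5,0,-2.5	./.:3,2:5:25:-2.5,0,-2.5	./.:3,2:5:25:-2.5,0,-2.5	./.:3,2:5:25:-2.5,0,-2.5	./.:3,2:5:25:-2.5,0,-2.5	./.:0,5:5:25:-10,-2.5,0	./.:0,5:5:25:-10,-2.5,0
chr1	4000	.	A	G	.	PASS	DP=600	GT:AD:DP:GQ:GL	./.:30,0:30:99:0,-9,-30	./.:30,0:30:99:0,-9,-30	./.:30,0:30:99:0,-9,-30	./.:30,0:30:99:0,-9,-30	./.:30,0:30:99:0,-9,-30	./.:30,0:30:99:0,-9,-30	./.:30,0:30:99:0,-9,-30	./.:30,0:30:99:0,-9,-30	./.:30,0:30:99:0,-9,-30	./.:30,0:30:99:0,-9,-30	./.:30,0:30:99:0,-9,-30	./.:30,0:30:99:0,-9,-30	./.:15,15:30:99:-9,0,-9	./.:15,15:30:99:-9,0,-9	./.:15,15:30:99:-9,0,-9	./.:15,15:30:99:-9,0,-9	./.:15,15:30:99:-9,0,-9	./.:15,15:30:99:-9,0,-9	./.:0,30:30:99:-30,-9,0	./.:0,30:30:99:-30,-9,0
chr1	5000	.	A	G	.	PASS	DP=400	GT:AD:DP:GQ:GL	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20
chr1	6000	.	A	G	.	PASS	DP=400	GT:AD:DP:GQ:GL	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:0,20:20:50:-20,-5,0	./.:0,20:20:50:-20,-5,0	./.:0,20:20:50:-20,-5,0	./.:0,20:20:50:-20,-5,0	./.:0,20:20:50:-20,-5,0	./.:0,20:20:50:-20,-5,0	./.:0,20:20:50:-20,-5,0	./.:0,20:20:50:-20,-5,0	./.:0,20:20:50:-20,-5,0	./.:0,20:20:50:-20,-5,0
chr1	7000	.	A	G	.	PASS	DP=400	GT:AD:DP:GQ:GL	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:0,20:20:50:-20,-5,0	./.:0,20:20:50:-20,-5,0
chr1	8000	.	A	G	.	PASS	DP=400	GT:AD:DP:GQ:GL	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:0,20:20:50:-20,-5,0	./.:0,20:20:50:-20,-5,0
chr1	9000	.	A	G	.	PASS	DP=400	GT:AD:DP:GQ:GL	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:0,20:20:50:-20,-5,0	./.:0,20:20:50:-20,-5,0	./.:0,20:20:50:-20,-5,0	./.:0,20:20:50:-20,-5,0	./.:0,20:20:50:-20,-5,0
chr1	10000	.	A	G	.	PASS	DP=400	GT:AD:DP:GQ:GL	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:20,0:20:50:0,-5,-20	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:10,10:20:50:-5,0,-5	./.:0,20:20:50:-20,-5,0
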