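gene_id	test_rep1	test_rep2	control_rep1	control_rep2
g00001	5.910758506738588	5.909028151472258	7.560693567562717	7.060407860661781
g00002	7.831674445692535	7.701618241077689	9.416617641877338	9.625991844914271
g00003	8.312606798670705	8.192041851092762	6.570352831795558	7.512007786730066
g00004	7.887022397668052	7.92458832215005	8.168626738409753	8.4302154986744
g00005	7.878932296588073	8.478474730454334	8.618438982619402	8.663823726212529
g00006	9.37535673502404	9.601398711470548	7.462485961040001	8.106520537402726
g00007	6.379010871474736	6.450775159695528	6.705268204947312	6.276387056985443
g00008	7.003443916402707	6.886074030018353	7.168723957459528	6.862640354409755
g00009	7.0561377083289285	6.8216058646767435	8.590601530639434	8.533170298015342
g00010	7.580029906876241	7.67008540217327	7.532816804712488	8.248371624104664
g00011	5.963467002274434	5.640496545276709	7.5473616277435704	7.451315555420733
g00012	7.218997592602928	7.8824122100063425	8.33440964123975	7.828764587132509
g00013	8.99258245002827	8.597796999427358	9.152151780669023	8.481564384988731
g00014	11.117322601186737	10.699907702967815	9.729598797918698	9.711140938025016
g00015	7.378029178869589	6.619988498563803	6.939678173048949	7.069652968676633
g00016	5.269353130646321	5.694456927274814	6.542069951233037	6.882665775982508
g00017	10.566107307851196	10.45931714084806	9.030592649527051	8.940304343384105
g00018	10.40263538829641	10.458145525788916	8.574035927340779	8.806893753682242
g00019	9.05716560285769	8.909305067079421	8.745723383838614	9.519524063877219
g00020	7.479175934135959	6.952838956768596	6.865792217207552	7.231923562809706
g00021	9.178451353568956	8.987830605324952	9.654793016598468	9.478142504827892
g00022	7.442954003775684	7.535531302702599	7.324441667205397	7.281638341273676
g00023	8.125744525184013	7.902077056277562	8.36191531152338	7.900130959863846
g00024	7.570786722947586	7.78135128351888	7.71489422892893	7.6646720461756885
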