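gene_id	test_rep1	test_rep2	control_rep1	control_rep2
g00001	4.762987421711448	5.1856659725498115	6.602065456037503	7.061656271052782
g00002	6.619923309438785	6.75161505323276	8.224642239922757	8.014512486291636
g00003	10.483766129530641	10.17055904140508	8.990523306848079	8.622487870543683
g00004	8.769195629910083	8.374060677688066	8.933624135024937	8.602134399140004
g00005	9.273196362907981	9.390515568312944	9.877563963709983	9.60767230803723
g00006	10.266413390868825	10.251282724671869	8.819324494317742	8.670648137277002
g00007	8.039980945291944	8.122118339242508	7.896793522252079	8.266034269828264
g00008	7.184914508096672	7.248035082642888	7.179945716599499	7.523916448153229
g00009	6.3287990387833055	6.634665867976316	7.793933216162681	7.769979045226525
g00010	6.516243578025076	7.215631861569974	7.4509634847997415	6.5296485212896735
g00011	7.4158476935424655	7.639860634623102	8.95479201442331	8.621986757977837
g00012	9.016774295812404	8.848742877126893	8.95546217463522	8.966113285523623
g00013	8.297019985203134	8.07538961177961	8.376899115099759	7.877845994737549
g00014	8.74335755582634	8.6013316859598	7.185953184657573	7.532529442269522
g00015	8.441348893252927	8.560480099291752	8.803185177267569	8.531740340600551
g00016	6.382269236698385	6.497288317935457	7.793395638386919	7.984465464812526
g00017	9.148937874932294	9.262995879138186	7.346020408406835	7.358732379114955
g00018	7.457373842373233	7.233856423432817	5.908525415863525	5.671287679168929
g00019	9.24997776596781	9.129423436267448	9.00625696370511	9.194872721654708
g00020	7.691758665377348	7.861200831245644	7.70829267205936	7.698067368069894
g00021	8.014065339850006	7.363540857064621	7.118122247023447	7.077477888802946
g00022	7.2210710490846655	7.660589175471394	7.52310550404879	7.615444554831597
g00023	8.324178122233535	8.362256327898406	8.856991043123642	8.245972391098544
g00024	8.757654900362022	8.593468194212713	8.536355435107843	8.591898681787251
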