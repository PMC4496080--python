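site_name,source,river,group_label,sr_ratio,sr_sd,n,pct_carboniferous,pct_tertiary,pct_precambrian,mean_age_ma,predicted,outlier,pred_interval
Amazon 13,Gaillardet et al. 1997,Amazon,Western Tributaries & Amazon Mainstem,0.710728,,1,1%,47%,21%,409,false,false,
Amazon 14,Gaillardet et al. 1997,Amazon,Western Tributaries & Amazon Mainstem,0.71112,,1,1%,47%,21%,409,false,false,
Amazon 20,Gaillardet et al. 1997,Amazon,Western Tributaries & Amazon Mainstem,0.711478,,1,2%,42%,25%,429,false,false,
Amazon 6,Gaillardet et al. 1997,Amazon,Western Tributaries & Amazon Mainstem,0.709172,,1,0%,60%,17%,407,false,false,
Rio Madeira,Gaillardet et al. 1997,Lower Madeira,Beni-Madeira & Lower Negro,0.720036,,1,2%,20%,30%,412,false,false,
Rio Negro,Gaillardet et al. 1997,Lower Negro,Beni-Madeira & Lower Negro,0.716223,,1,0%,21%,68%,1243,false,false,
Rio Topajos,Gaillardet et al. 1997,Lower Topajos,Lower Amazon Tributaries,0.733172,,1,10%,8%,48%,658,false,false,
Rio Trombetas,Gaillardet et al. 1997,Lower Trombetas,Lower Amazon Tributaries,0.732295,,1,3%,7%,78%,515,false,false,
Uracara,Gaillardet et al. 1997,Lower Uracara,Lower Amazon Tributaries,0.723584,,1,2%,19%,62%,558,false,false,
Purus,Queiroz et al. 2009,Lower Purus,Western Tributaries & Amazon Mainstem,0.711135,,1,0%,92%,4%,564,false,false,
Solimoes,Queiroz et al. 2009,Lower Solimoes,Western Tributaries & Amazon Mainstem,0.714461,,1,0%,63%,1%,289,false,true,
Atalaya,Santos et al. 2013,Upper Solimoes,Western Tributaries & Amazon Mainstem,0.70887,,1,0%,20%,0%,331,false,false,
Borba,Santos et al. 2013,Lower Madeira,Beni-Madeira & Lower Negro,0.71762,,1,2%,20%,30%,412,false,false,
Borja,Santos et al. 2013,Upper Solimoes,Western Tributaries & Amazon Mainstem,0.7085,,1,0%,13%,0%,426,false,false,
Caracarai,Santos et al. 2013,Upper Negro,Beni-Madeira & Lower Negro,0.72238,,1,0%,0%,74%,1650,false,false,
Francisco de Orellana,Santos et al. 2013,Upper Solimoes,Western Tributaries & Amazon Mainstem,0.70592,0.00037,26,0%,67%,10%,287,false,false,
Itiatuba,Santos et al. 2013,Lower Tapajos,Lower Amazon Tributaries,0.72964,0.00587,27,10%,4%,51%,671,false,false,
LaBrea,Santos et al. 2013,Lower Purus,Western Tributaries & Amazon Mainstem,0.71012,,1,0%,90%,6%,1126,false,false,
Manacapuru,Santos et al. 2013,Lower Solimoes,Western Tributaries & Amazon Mainstem,0.70907,0.00025,38,0%,72%,2%,312,false,false,
Obidos,Santos et al. 2013,Amazon,Western Tributaries & Amazon Mainstem,0.71154,0.00053,46,1%,46%,23%,408,false,false,
PortoVelho,Santos et al. 2013,Lower Madeira,Beni-Madeira & Lower Negro,0.71677,0.00073,9,3%,17%,22%,379,false,false,
Ruranbaque,Santos et al. 2013,Upper Madeira,Beni-Madeira & Lower Negro,0.71730,0.00126,38,17%,13%,1%,433,false,false,
Serrinha,Santos et al. 2013,Upper Negro,Lower Amazon Tributaries,0.73183,0.00737,16,0%,19%,80%,614,false,false,
Tabitinga,Santos et al. 2013,Upper Solimoes,Western Tributaries & Amazon Mainstem,0.70881,0.00029,9,0%,75%,3%,200,false,false,
Amazon Mouth (Predicted),Predicted from regression,Amazon,Western Tributaries & Amazon Mainstem,0.71625,,,2%,40%,29%,482,true,false,0.00787
Jari (Predicted),Predicted from regression,Lower Jari,Lower Amazon Tributaries,0.72928,,,0%,2%,89%,718,true,false,0.00873
Paru (Predicted),Predicted from regression,Lower Paru,Lower Amazon Tributaries,0.72703,,,1%,4%,78%,515,true,false,0.00845
Tocantins (Predicted),Predicted from regression,Lower Tocantins,Lower Amazon Tributaries,0.72683,,,13%,22%,36%,877,true,false,0.00884
Xingu (Predicted),Predicted from regression,Lower Xingu,Lower Amazon Tributaries,0.72633,,,2%,13%,70%,1091,true,false,0.00827
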