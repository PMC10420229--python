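# Per-micelle descriptor subsets used in the published SVM models.
# The names follow the AlvaDesc nomenclature; users with access to that
# descriptor set can pass these lists straight to svm_regress.
SC:
  - Mv
  - RBN
  - RBF
  - "H%"
  - "N%"
  - "O%"
  - NRS
  - nR09
  - nR10
  - X4Av
  - P_VSA_LogP_2
  - P_VSA_s_4
  - P_VSA_ppp_P
  - P_VSA_charge_1
  - P_VSA_charge_3
  - P_VSA_charge_4
  - P_VSA_charge_5
  - P_VSA_charge_13
  - P_VSA_charge_14
HTAB:
  - nSK
  - nH
  - "N%"
  - Xu
  - S1K
  - DELS
  - BAC
  - X0
  - X0sol
  - P_VSA_LogP_1
  - P_VSA_LogP_4
  - P_VSA_LogP_6
  - P_VSA_LogP_8
  - P_VSA_MR_5
  - P_VSA_m_5
  - P_VSA_s_3
  - P_VSA_ppp_D
  - P_VSA_charge_2
  - P_VSA_charge_4
  - P_VSA_charge_5
  - P_VSA_charge_6
  - P_VSA_charge_9
  - P_VSA_charge_12
  - P_VSA_charge_14
  - qpmax
  - qnmax
  - Qpos
  - Qneg
  - Qtot
  - Qmean
  - Q2
  - RPCG
  - RNCG
  - TPSA(NO)
  - TPSA(Tot)
LPFOS:
  - RBF
  - nTB
  - MaxTD
  - P_VSA_LogP_2
  - P_VSA_LogP_3
  - P_VSA_LogP_4
  - P_VSA_MR_2
  - P_VSA_s_3
  - P_VSA_charge_2
  - P_VSA_charge_6
  - P_VSA_charge_7
  - P_VSA_charge_9
  - P_VSA_charge_13
  - P_VSA_charge_14
  - Qmean
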